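"""Small packaged reference tables."""

from importlib import resources

import pandas as pd

__all__ = ["load_ukb_cause_of_death", "cause_share"]


def load_ukb_cause_of_death() -> pd.DataFrame:
    """Cause-of-death tallies for the deceased of the exome-sequenced UK
    Biobank analysis cohort (1,122 deaths within the 11-year follow-up)."""
    with resources.files("ptvburden.data").joinpath("ukb_cause_of_death.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def cause_share(table: pd.DataFrame, cause: str) -> float:
    """Percentage of deaths attributed to ``cause``."""
    total = table["deaths"].sum()
    row = table.loc[table["cause"] == cause, "deaths"]
    if row.empty:
        raise KeyError(f"unknown cause {cause!r}")
    return float(100.0 * row.iloc[0] / total)
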