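"""Published per-cohort classification summaries bundled with the package.

Four sorafenib-resistance signatures (Huh7-R-A7, HepG2-R, HCC-3sp-R,
Xeno-R) were evaluated by nearest-template prediction across six public
HCC microarray cohorts; the reported per-cohort percentage of
signature-positive tumors and tumor-vs-normal sensitivity/specificity are
shipped as a reference table so the across-cohort summary statistics can
be recomputed locally.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .ntp import mean_across_datasets

__all__ = ["load_cohort_reference", "summarize_cohort_reference"]


def load_cohort_reference() -> pd.DataFrame:
    """Per-signature, per-cohort reported classification statistics."""
    with resources.files("sigrev.data").joinpath("cohort_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def summarize_cohort_reference(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Across-cohort means per signature, at the reported precision:
    signature-positive percentage to 1 decimal, sensitivity/specificity to 2."""
    if table is None:
        table = load_cohort_reference()
    rows = []
    for sig, sub in table.groupby("signature", sort=False):
        rows.append(
            {
                "signature": sig,
                "mean_pct_positive": mean_across_datasets(sub["pct_positive"], decimals=1),
                "mean_sensitivity": mean_across_datasets(sub["sensitivity"], decimals=2),
                "mean_specificity": mean_across_datasets(sub["specificity"], decimals=2),
                "n_datasets": len(sub),
            }
        )
    return pd.DataFrame(rows)
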