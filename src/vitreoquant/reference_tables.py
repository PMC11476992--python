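"""Bundled published reference table of growth-related vitreous DEPs.

The package ships the printed fold-change table of the 14 growth-related
chick vitreous proteins called differentially expressed across all three
day-vs-day-7 contrasts (days 14, 21, 28; right-eye OD and left-eye OS
fold changes plus the reported mean +/- SD, all rounded to 2 decimals as
printed).  It serves as a fixed numeric regression target for the
bilateral filter and the mean/SD derivation: the printed OD/OS cells are
*inputs*, from which the AVE/SD columns can be re-derived and the filter
membership re-checked.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_growth_dep_table", "CONTRAST_DAYS"]

CONTRAST_DAYS = (14, 21, 28)


def load_growth_dep_table() -> pd.DataFrame:
    """Return the reference table indexed by UniProt accession.

    Columns per contrast day d in (14, 21, 28): ``fc_od_<d>``,
    ``fc_os_<d>`` (per-eye fold changes vs day 7), ``ave_<d>`` and
    ``sd_<d>`` (printed mean and two-value SD), plus ``protein_name``
    and ``gene``.
    """
    ref = resources.files("vitreoquant.data") / "growth_dep_table.tsv"
    with resources.as_file(ref) as path:
        table = pd.read_csv(path, sep="\t", index_col="accession")
    return table
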