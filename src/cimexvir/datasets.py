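"""Packaged reference tables.

Small plain-text tables transcribed from a worldwide bed bug (Cimex) virome
survey, used as worked-example inputs and regression fixtures:

* the published pairwise p-distance matrix (percent) among Cimex tenui-like
  virus 1 RdRp coding sequences plus three tenuivirus outgroups (RHBTV = Rice
  hoja blanca tenuivirus, RSV = Rice stripe virus, MSTV = Maize stripe
  tenuivirus), with the Italy / rest-of-the-world / outgroup clade labels;
* the survey's published group-mean p-distances for that family (percent),
  kept as the expectation table for the group-summary worked example;
* the per-sample read-mapping percentages (virus vs Wolbachia) for the 22
  sequenced bed bugs, the input of the abundance regression.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_rdrp_distance_matrix",
    "load_rdrp_groups",
    "load_rdrp_group_mean_reference",
    "load_read_percentages",
]


def _path(name: str):
    return resources.files("cimexvir") / "data" / name


def load_rdrp_distance_matrix() -> pd.DataFrame:
    """Published RdRp pairwise p-distance matrix, percent, symmetric."""
    from .io import read_distance_matrix
    return read_distance_matrix(_path("tenui_rdrp_pdistances_pct.tsv"))


def load_rdrp_groups() -> dict[str, str]:
    """Clade labels (Italy / Rest of the World / Outgroup) for the matrix IDs."""
    from .io import read_groups
    return read_groups(_path("tenui_rdrp_groups.tsv"))


def load_rdrp_group_mean_reference() -> pd.DataFrame:
    """Published within/between-clade mean p-distances, percent."""
    return pd.read_csv(_path("tenui_rdrp_group_means_pct.tsv"), sep="\t")


def load_read_percentages() -> pd.DataFrame:
    """Per-sample percent reads mapped to viruses and to Wolbachia (22 samples)."""
    from .io import read_abundance_table
    return read_abundance_table(_path("wolbachia_virus_read_pct.tsv"))
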