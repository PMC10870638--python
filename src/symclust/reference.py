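"""Bundled reference tables from a large observational oncology sample.

Two kinds of comparator data ship with the package, both for the 38-item
modified MSAS catalog and an age dichotomy at 60 years (younger n=741,
older n=602):

* per-group symptom occurrence percentages, and
* per-group rotated factor loading tables for the eight-cluster solution
  (unweighted least squares extraction, geomin rotation; only loadings
  meeting the 0.40 reporting rule are nonzero).

They serve as worked examples and as inputs to the comparator stage when no
patient-level data are available.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .catalog import default_catalog

__all__ = [
    "GROUP_SIZES",
    "SCREENED",
    "ENROLLED",
    "reference_occurrence_rates",
    "reference_loadings",
    "CLUSTER_LABELS",
]

#: Younger / older group sizes in the reference sample.
GROUP_SIZES = {"younger": 741, "older": 602}
#: Patients approached and patients consenting in the reference sample.
SCREENED = 2234
ENROLLED = 1343

#: Display names for the eight reference clusters.
CLUSTER_LABELS = {
    "fatigue": "Physical and cognitive fatigue",
    "respiratory": "Respiratory",
    "psychological": "Psychological",
    "hormonal": "Hormonal",
    "chemo_toxicity": "Chemotherapy-related toxicity",
    "weight_gain": "Weight gain",
    "gastrointestinal": "Gastrointestinal",
    "epithelial": "Epithelial",
}


def _data_path(name: str):
    return resources.files("symclust.data") / name


def reference_occurrence_rates() -> pd.DataFrame:
    """Occurrence rates by age group, indexed by item code.

    Returns a frame with columns ``pct_younger`` / ``pct_older`` (percent)
    and ``rate_younger`` / ``rate_older`` (proportions).
    """
    with resources.as_file(_data_path("occurrence_rates_by_age.csv")) as path:
        df = pd.read_csv(path).set_index("code")
    expected = default_catalog().codes
    if list(df.index) != expected:
        raise ValueError("bundled occurrence table does not match the default catalog")
    df["rate_younger"] = df["pct_younger"] / 100.0
    df["rate_older"] = df["pct_older"] / 100.0
    return df


def reference_loadings(group: str) -> pd.DataFrame:
    """Rotated loading table (items x 8 clusters) for ``'younger'`` or ``'older'``."""
    if group not in GROUP_SIZES:
        raise ValueError(f"group must be 'younger' or 'older', got {group!r}")
    with resources.as_file(_data_path(f"loadings_{group}.tsv")) as path:
        df = pd.read_csv(path, sep="\t").set_index("item")
    return df
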