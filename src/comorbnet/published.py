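"""Transcribed result tables from the motivating IBD/NASH comparison.

These small fixtures carry the *published output lists* (shared hubs and
bottlenecks of the two disease interactomes, the common-network hub and
bottleneck lists, and the enriched-term table for the seven key genes) so
the role-intersection, key-gene and grouping logic can be exercised against
printed results.  The underlying database snapshots are not available, so
these tables are documentation-grade inputs, never recomputation targets.

Note: the source report is internally inconsistent about the fifth
common-network bottleneck (TLR2 in one passage, TLR4 in the table and
abstract); the transcription follows the table.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "reported_shared_roles",
    "reported_common_roles",
    "reported_enrichment",
    "shared_hub_set",
    "shared_bottleneck_set",
    "common_hub_set",
    "common_bottleneck_set",
]


def _read(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("comorbnet.data") / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, **kwargs)


def reported_shared_roles() -> pd.DataFrame:
    """Shared hub/bottleneck table of the two disease networks.

    Columns: hub, hub_degree, starred, bottleneck, bottleneck_betweenness;
    the bottleneck columns are populated only on the first three rows.  The
    hub_degree column is not attributed to a specific network in the source
    and is carried as documentation only.
    """
    return _read("reported_shared_roles.tsv")


def reported_common_roles() -> pd.DataFrame:
    """Common-network hub and bottleneck lists with their printed scores."""
    return _read("reported_common_roles.tsv")


def reported_enrichment() -> pd.DataFrame:
    """Enriched-term table for the seven key genes.

    The printed group label appears only on the first row of each group
    block; blank cells mean the label carries over from the row above.
    """
    df = _read("reported_enrichment.tsv")
    df["group_filled"] = df["group"].replace("", pd.NA).ffill()
    return df


def shared_hub_set() -> frozenset[str]:
    df = reported_shared_roles()
    return frozenset(h for h in df["hub"] if h)


def shared_bottleneck_set() -> frozenset[str]:
    df = reported_shared_roles()
    return frozenset(b for b in df["bottleneck"] if b)


def common_hub_set() -> frozenset[str]:
    df = reported_common_roles()
    return frozenset(h for h in df["hub"] if h)


def common_bottleneck_set() -> frozenset[str]:
    df = reported_common_roles()
    return frozenset(b for b in df["bottleneck"] if b)
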