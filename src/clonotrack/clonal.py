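"""Clonal expansion detection among antigen-specific single cells.

An expansion is a within-donor group of >= 2 cells sharing an identical
nucleotide CDR3 — at the beta-chain level (``TRB_nt``) or requiring identity
of both beta and alpha chains (``TRB_and_TRA_nt``).  Identity across donors is
publicity, not expansion, and is handled by the track-back module.  Expansion
groups are then summarised by how they spread across gene-expression clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .repertoire_io import ScClonotype

logger = logging.getLogger(__name__)

MATCH_LEVELS = ("TRB_nt", "TRB_and_TRA_nt")


@dataclass
class ExpansionGroup:
    group_id: str
    member_cell_ids: list[str]
    match_level: str
    donor_id: str
    member_clusters: list[Optional[int]]
    single_cluster: Optional[bool] = None

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)

    @property
    def clusters_spanned(self) -> set[int]:
        return {c for c in self.member_clusters if c is not None}


def find_expansions(cells: Sequence[ScClonotype], level: str = "TRB_nt",
                    min_size: int = 2) -> list[ExpansionGroup]:
    """Group cells by exact nucleotide identity at the requested level.

    Grouping is within donor; only groups of >= ``min_size`` cells are
    returned (the threshold is configurable because reports differ on
    whether a pair already counts as an expansion).  At the
    ``TRB_and_TRA_nt`` level, cells lacking an alpha chain cannot join a
    group.
    """
    if level not in MATCH_LEVELS:
        raise ValueError(f"unknown match level {level!r}")
    groups: dict[tuple, list[ScClonotype]] = {}
    for cell in cells:
        if level == "TRB_and_TRA_nt":
            if not cell.cdr3a_nt:
                continue
            key = (cell.donor_id, cell.cdr3b_nt, cell.cdr3a_nt)
        else:
            key = (cell.donor_id, cell.cdr3b_nt)
        groups.setdefault(key, []).append(cell)
    out: list[ExpansionGroup] = []
    for i, (key, members) in enumerate(sorted(groups.items())):
        if len(members) < min_size:
            continue
        out.append(
            ExpansionGroup(
                group_id=f"{level}:{key[0]}:{len(out) + 1}",
                member_cell_ids=[c.cell_id for c in members],
                match_level=level,
                donor_id=key[0],
                member_clusters=[c.genex_cluster for c in members],
            )
        )
    return out


@dataclass
class ClusterSpanSummary:
    n_groups: int
    n_labelled: int
    n_single_cluster: int
    fraction_single_cluster: float


def expansion_cluster_span(groups: Sequence[ExpansionGroup],
                           labels: Optional[Mapping[str, int]] = None) -> ClusterSpanSummary:
    """Fraction of expansion groups confined to one gene-expression cluster.

    ``labels`` (cell_id -> cluster) overrides clusters stored on the cells.
    Groups with any unlabelled member are excluded from the denominator with
    a log entry.
    """
    n_single = 0
    n_labelled = 0
    for g in groups:
        if labels is not None:
            member_clusters = [labels.get(c) for c in g.member_cell_ids]
        else:
            member_clusters = g.member_clusters
        fully_labelled = all(c is not None for c in member_clusters)
        if not fully_labelled:
            logger.info("expansion group %s excluded: unlabelled member(s)", g.group_id)
            g.single_cluster = None
            continue
        n_labelled += 1
        g.single_cluster = len(set(member_clusters)) == 1
        if g.single_cluster:
            n_single += 1
    frac = n_single / n_labelled if n_labelled else float("nan")
    return ClusterSpanSummary(
        n_groups=len(groups), n_labelled=n_labelled,
        n_single_cluster=n_single, fraction_single_cluster=frac,
    )


def load_specificity_groups(path) -> dict[str, str]:
    """Load externally produced specificity-group assignments (cell_id -> group).

    Motif-based specificity grouping itself is out of scope; this loader
    accepts a two-column TSV (cell_id, group_id) so group-level summaries can
    still run on external output.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_id", "group_id"} <= set(df.columns):
        raise ValueError("specificity group file needs cell_id and group_id columns")
    return dict(zip(df["cell_id"], df["group_id"]))
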