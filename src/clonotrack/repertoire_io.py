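"""Reading, writing and validation of clonotype tables and bulk repertoires.

Two kinds of input drive the analysis:

* antigen-specific *single-cell* clonotype tables — one row per sorted cell,
  carrying the TRB (and optionally TRA) CDR3 at nucleotide and amino-acid
  resolution plus donor/cohort/specificity metadata;
* *bulk* TCRB repertoires — AIRR Rearrangement TSV files, one per
  donor x peripheral subset (TN, CM, Treg, Tscm), with per-clone read counts.

Sequences are normalised to upper case on read.  Clonotype identity inside a
bulk repertoire is the (cdr3_nt, v_call, j_call) tuple; the ``junction`` column
is the CDR3 including the conserved C and F/W anchors, stored verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

COHORTS = ("HD", "T1D")
SPECIFICITIES = ("GAD", "CMV")
SUBSETS = ("TN", "CM", "Treg", "Tscm")
PHENOTYPES = ("TN", "CM", "EM", "NTEM", "Tscm")

_DNA = frozenset("ACGT")

#: Columns an AIRR Rearrangement TSV must provide for bulk repertoires.
AIRR_REQUIRED = ("junction", "junction_aa", "v_call", "j_call", "duplicate_count")

SC_REQUIRED = ("cell_id", "donor_id", "cohort", "specificity",
               "cdr3b_nt", "cdr3b_aa", "v_gene_b", "j_gene_b")
SC_OPTIONAL = ("cdr3a_nt", "cdr3a_aa", "phenotype", "genex_cluster")


class FormatError(ValueError):
    """A file violates the expected tabular contract (e.g. missing column)."""


class RowError(ValueError):
    """A single row is malformed; carries the offending 0-based row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class OutOfFrameError(ValueError):
    """CDR3 nucleotide length is not a multiple of three."""


def translate_cdr3(nt: str) -> str:
    """Translate a CDR3 nucleotide sequence with the standard genetic code.

    The reading frame starts at the first base; stop codons are rendered
    as ``"*"``.  Raises :class:`OutOfFrameError` if the length is not a
    multiple of 3, and ``ValueError`` on non-ACGT characters.
    """
    nt = nt.upper()
    if len(nt) == 0 or len(nt) % 3 != 0:
        raise OutOfFrameError(f"out-of-frame CDR3 (length {len(nt)})")
    bad = set(nt) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in CDR3: {sorted(bad)}")
    return str(Seq(nt).translate())


def is_productive(nt: str) -> bool:
    """True iff ``nt`` is in frame and its translation contains no stop.

    Malformed input (empty, non-ACGT) returns False with a warning rather
    than raising, so bulk scans never abort on a single bad record.
    """
    try:
        return "*" not in translate_cdr3(nt)
    except ValueError:
        logger.warning("non-translatable CDR3 treated as unproductive: %r", nt)
        return False


@dataclass(frozen=True)
class ScClonotype:
    """One antigen-specific single cell: receptor chains plus metadata."""

    cell_id: str
    donor_id: str
    cohort: str
    specificity: str
    cdr3b_nt: str
    cdr3b_aa: str
    v_gene_b: str
    j_gene_b: str
    cdr3a_nt: Optional[str] = None
    cdr3a_aa: Optional[str] = None
    phenotype: Optional[str] = None
    genex_cluster: Optional[int] = None

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise FormatError(f"unknown cohort {self.cohort!r}")
        if self.specificity not in SPECIFICITIES:
            raise FormatError(f"unknown specificity {self.specificity!r}")
        if self.phenotype is not None and self.phenotype not in PHENOTYPES:
            raise FormatError(f"unknown phenotype {self.phenotype!r}")


@dataclass(frozen=True)
class Clone:
    """One bulk clone: nucleotide/amino-acid CDR3, V/J calls and read count."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    count: int


@dataclass
class BulkRepertoire:
    """One donor x subset bulk TCRB repertoire with per-clone counts.

    ``(cdr3_nt, v_call, j_call)`` tuples are unique; clone frequency is
    ``count / total_count``.  Lookup indices for tracking are built lazily
    and cached.
    """

    donor_id: str
    cohort: str
    subset: str
    clones: list[Clone]
    total_count: int = 0

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise FormatError(f"unknown cohort {self.cohort!r}")
        if self.subset not in SUBSETS:
            raise FormatError(f"unknown subset {self.subset!r}")
        if not self.total_count:
            self.total_count = sum(c.count for c in self.clones)
        if self.total_count != sum(c.count for c in self.clones):
            raise ValueError("total_count does not equal the sum of clone counts")
        keys = {(c.cdr3_nt, c.v_call, c.j_call) for c in self.clones}
        if len(keys) != len(self.clones):
            raise ValueError("duplicate (cdr3_nt, v_call, j_call) within repertoire")
        self._nt_freq: Optional[dict[str, float]] = None
        self._aa_index: Optional[dict[str, dict[str, float]]] = None

    def frequency(self, clone: Clone) -> float:
        return clone.count / self.total_count

    def nt_frequencies(self) -> dict[str, float]:
        """Summed frequency per nucleotide CDR3 (V/J records collapsed)."""
        if self._nt_freq is None:
            acc: dict[str, float] = {}
            for c in self.clones:
                acc[c.cdr3_nt] = acc.get(c.cdr3_nt, 0.0) + c.count
            self._nt_freq = {nt: n / self.total_count for nt, n in acc.items()}
        return self._nt_freq

    def aa_index(self) -> dict[str, dict[str, float]]:
        """Map amino-acid CDR3 -> {nucleotide variant -> summed frequency}."""
        if self._aa_index is None:
            idx: dict[str, dict[str, float]] = {}
            for nt, f in self.nt_frequencies().items():
                aa = translate_cdr3(nt)
                idx.setdefault(aa, {})[nt] = f
            self._aa_index = idx
        return self._aa_index


@dataclass
class RepertoireSet:
    """Collection of bulk repertoires keyed by (donor_id, subset)."""

    repertoires: dict[tuple[str, str], BulkRepertoire] = field(default_factory=dict)

    def add(self, rep: BulkRepertoire) -> None:
        key = (rep.donor_id, rep.subset)
        if key in self.repertoires:
            raise ValueError(f"duplicate repertoire for {key}")
        self.repertoires[key] = rep

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[BulkRepertoire]:
        return iter(self.repertoires.values())

    def by_subset(self, subset: str) -> list[BulkRepertoire]:
        return [r for (_, s), r in self.repertoires.items() if s == subset]

    def subset_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in SUBSETS}
        for (_, s) in self.repertoires:
            counts[s] += 1
        return counts

    def donor_cohort(self, donor_id: str) -> str:
        for (d, _), rep in self.repertoires.items():
            if d == donor_id:
                return rep.cohort
        raise KeyError(donor_id)


def read_bulk_repertoire(path, donor_id: str, cohort: str, subset: str) -> BulkRepertoire:
    """Read one AIRR Rearrangement TSV into a :class:`BulkRepertoire`.

    Rows with ``duplicate_count <= 0`` or an empty junction are rejected;
    rows sharing (junction, v_call, j_call) are merged by summing counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in AIRR_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    clones: dict[tuple[str, str, str], list] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        junction = row.junction.strip().upper()
        if not junction:
            continue
        if set(junction) - _DNA:
            raise RowError(f"non-DNA characters in junction {junction!r}", i)
        try:
            count = int(row.duplicate_count)
        except ValueError as exc:
            raise RowError(f"non-integer duplicate_count {row.duplicate_count!r}", i) from exc
        if count <= 0:
            continue
        aa = row.junction_aa.strip().upper() or translate_cdr3(junction)
        key = (junction, row.v_call, row.j_call)
        if key in clones:
            clones[key][4] += count
        else:
            clones[key] = [junction, aa, row.v_call, row.j_call, count]
    records = [Clone(*v[:4], count=v[4]) for v in clones.values()]
    return BulkRepertoire(donor_id=donor_id, cohort=cohort, subset=subset, clones=records)


def write_bulk_repertoire(rep: BulkRepertoire, path) -> None:
    """Write an AIRR Rearrangement TSV, rows sorted by descending count then sequence."""
    rows = sorted(rep.clones, key=lambda c: (-c.count, c.cdr3_nt, c.v_call, c.j_call))
    df = pd.DataFrame(
        {
            "junction": [c.cdr3_nt for c in rows],
            "junction_aa": [c.cdr3_aa for c in rows],
            "v_call": [c.v_call for c in rows],
            "j_call": [c.j_call for c in rows],
            "duplicate_count": [c.count for c in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sc_clonotypes(path) -> list[ScClonotype]:
    """Read a single-cell clonotype TSV, keeping productive beta chains only.

    Cells lacking a beta CDR3, or whose beta CDR3 is unproductive, are
    dropped with a logged count.  ``cdr3b_aa``, when empty, is filled by
    translation.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in SC_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    cells: list[ScClonotype] = []
    n_dropped = 0
    for row in df.itertuples(index=False):
        nt = row.cdr3b_nt.strip().upper()
        if not nt or not is_productive(nt):
            n_dropped += 1
            continue
        aa = row.cdr3b_aa.strip().upper() or translate_cdr3(nt)
        kwargs = dict(
            cell_id=row.cell_id, donor_id=row.donor_id, cohort=row.cohort,
            specificity=row.specificity, cdr3b_nt=nt, cdr3b_aa=aa,
            v_gene_b=row.v_gene_b, j_gene_b=row.j_gene_b,
        )
        for col in SC_OPTIONAL:
            val = getattr(row, col, "")
            val = val.strip() if isinstance(val, str) else val
            if val in ("", None):
                continue
            if col == "genex_cluster":
                kwargs[col] = int(val)
            elif col in ("cdr3a_nt", "cdr3a_aa"):
                kwargs[col] = str(val).upper()
            else:
                kwargs[col] = val
        cells.append(ScClonotype(**kwargs))
    if n_dropped:
        logger.info("dropped %d cells without a productive beta CDR3", n_dropped)
    return cells


def write_sc_clonotypes(cells: Sequence[ScClonotype], path) -> None:
    """Write a single-cell clonotype TSV with deterministic column/row order."""
    rows = sorted(cells, key=lambda c: (c.donor_id, c.cell_id))
    df = pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "donor_id": c.donor_id,
                "cohort": c.cohort,
                "specificity": c.specificity,
                "cdr3b_nt": c.cdr3b_nt,
                "cdr3b_aa": c.cdr3b_aa,
                "v_gene_b": c.v_gene_b,
                "j_gene_b": c.j_gene_b,
                "cdr3a_nt": c.cdr3a_nt or "",
                "cdr3a_aa": c.cdr3a_aa or "",
                "phenotype": c.phenotype or "",
                "genex_cluster": "" if c.genex_cluster is None else c.genex_cluster,
            }
            for c in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
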