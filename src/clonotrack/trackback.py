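"""Track-back of antigen-specific clonotypes into bulk peripheral repertoires.

The central operation of the package: each single-cell TCRB CDR3 (the *query*)
is searched in every bulk repertoire, at nucleotide or amino-acid resolution.
Matching is CDR3-only — the published search imposes no V/J condition — with a
strict mode requiring V-gene equality available behind a flag.

At the nucleotide level a hit's frequency is the summed frequency of all bulk
records carrying the query sequence.  At the amino-acid level several
nucleotide sequences may encode the query CDR3 ("convergence"); the hit
frequency is the arithmetic mean of the per-nucleotide-variant frequencies and
the convergence is the number of distinct variants.

Publicity of a clonotype in a subset is the percentage of searched repertoires
containing it:

* extremely public — present in >= 75% of repertoires;
* public — 25.0%-74.9%;
* ultraprivate — a single hit, and only in the clonotype's source donor;
* private — everything else below 25%.

The denominator always comes from the searched :class:`RepertoireSet`, never
from a constant (31 TN / 31 CM / 16 Treg / 16 Tscm in the emulated design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire_io import BulkRepertoire, RepertoireSet, ScClonotype, SUBSETS

logger = logging.getLogger(__name__)

PUBLICITY_CATEGORIES = ("extremely_public", "public", "private", "ultraprivate")


@dataclass(frozen=True)
class TrackHit:
    """Presence of one query clonotype in one repertoire."""

    query_id: str
    level: str            # "nt" | "aa"
    donor_id: str
    subset: str
    found: bool
    frequency: float
    convergence: int      # distinct nt variants (aa level); 1 when found at nt level


def _check_reps(reps: RepertoireSet) -> None:
    if len(reps) == 0:
        raise ValueError("empty RepertoireSet")


def track_nt(query: ScClonotype, reps: RepertoireSet,
             strict_v: bool = False) -> list[TrackHit]:
    """One hit per repertoire: exact nucleotide CDR3 match, frequencies summed."""
    _check_reps(reps)
    hits = []
    for rep in reps:
        if strict_v:
            freq = sum(
                rep.frequency(c) for c in rep.clones
                if c.cdr3_nt == query.cdr3b_nt and c.v_call == query.v_gene_b
            )
        else:
            freq = rep.nt_frequencies().get(query.cdr3b_nt, 0.0)
        hits.append(TrackHit(
            query_id=query.cdr3b_nt, level="nt", donor_id=rep.donor_id,
            subset=rep.subset, found=freq > 0.0, frequency=freq,
            convergence=1 if freq > 0.0 else 0,
        ))
    return hits


def track_aa(query: ScClonotype, reps: RepertoireSet,
             strict_v: bool = False) -> list[TrackHit]:
    """One hit per repertoire: amino-acid match with convergence counting.

    The convergent set is keyed by distinct nucleotide sequence; records that
    share one nucleotide sequence have their frequencies summed before the
    arithmetic mean across variants is taken.
    """
    _check_reps(reps)
    hits = []
    for rep in reps:
        if strict_v:
            variants: dict[str, float] = {}
            for c in rep.clones:
                if c.cdr3_aa == query.cdr3b_aa and c.v_call == query.v_gene_b:
                    variants[c.cdr3_nt] = variants.get(c.cdr3_nt, 0.0) + rep.frequency(c)
        else:
            variants = rep.aa_index().get(query.cdr3b_aa, {})
        k = len(variants)
        freq = float(np.mean(list(variants.values()))) if k else 0.0
        hits.append(TrackHit(
            query_id=query.cdr3b_aa, level="aa", donor_id=rep.donor_id,
            subset=rep.subset, found=k > 0, frequency=freq, convergence=k,
        ))
    return hits


def unique_queries(cells: Sequence[ScClonotype], level: str) -> list[ScClonotype]:
    """Collapse duplicate cells to unique clonotypes before tracking.

    Uniqueness is per (donor, sequence) at the requested level, keeping the
    first cell carrying each clonotype.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for c in cells:
        key = (c.donor_id, c.cdr3b_nt if level == "nt" else c.cdr3b_aa)
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out


def track_all(cells: Sequence[ScClonotype], reps: RepertoireSet, level: str,
              strict_v: bool = False) -> pd.DataFrame:
    """Track every unique clonotype; tidy frame, one row per (query, repertoire)."""
    if level not in ("nt", "aa"):
        raise ValueError(f"unknown tracking level {level!r}")
    fn = track_nt if level == "nt" else track_aa
    rows = []
    for q in unique_queries(cells, level):
        for h in fn(q, reps, strict_v=strict_v):
            rows.append({
                "query_id": h.query_id, "source_donor": q.donor_id,
                "source_cohort": q.cohort, "level": level,
                "rep_donor": h.donor_id, "rep_subset": h.subset,
                "found": h.found, "frequency": h.frequency,
                "convergence": h.convergence,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Publicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PublicityRecord:
    query_id: str
    subset: str
    n_repertoires_searched: int
    n_found: int
    pct: float
    category: str
    source_donor_only: bool


def classify_publicity(n_found: int, n_repertoires: int,
                       source_donor_hit_only: bool) -> str:
    """Map a hit count to a publicity category (found clonotypes only)."""
    if n_repertoires < 1:
        raise ValueError("n_repertoires must be >= 1")
    if not 0 < n_found <= n_repertoires:
        raise ValueError(f"n_found must be in 1..{n_repertoires}, got {n_found}")
    pct = 100.0 * n_found / n_repertoires
    if pct >= 75.0:
        return "extremely_public"
    if pct >= 25.0:
        return "public"
    if n_found == 1 and source_donor_hit_only:
        return "ultraprivate"
    return "private"


def publicity_records(hits: pd.DataFrame, subset: str) -> list[PublicityRecord]:
    """Per-clonotype publicity in one subset from a tidy aa hit table.

    ``hits`` is the output of :func:`track_all`; a clonotype found in zero
    repertoires of the subset gets no record.
    """
    sub = hits[hits["rep_subset"] == subset]
    n_reps = sub["rep_donor"].nunique()
    out = []
    for qid, grp in sub.groupby("query_id", sort=True):
        found = grp[grp["found"]]
        if found.empty:
            continue
        source_donors = set(grp["source_donor"])
        hit_donors = set(found["rep_donor"])
        source_only = hit_donors <= source_donors
        n_found = len(hit_donors)
        out.append(PublicityRecord(
            query_id=qid, subset=subset, n_repertoires_searched=n_reps,
            n_found=n_found, pct=100.0 * n_found / n_reps,
            category=classify_publicity(n_found, n_reps, source_only and n_found == 1),
            source_donor_only=source_only,
        ))
    return out


# ---------------------------------------------------------------------------
# Tracking rate
# ---------------------------------------------------------------------------

@dataclass
class TrackingRateSummary:
    per_donor: dict[str, float]   # percentage per source donor
    mean: float
    sd: float                     # sample sd (ddof=1); nan with one donor


def tracking_rate(cells: Sequence[ScClonotype], reps: RepertoireSet,
                  level: str) -> TrackingRateSummary:
    """Per source donor: % of unique clonotypes found in >= 1 repertoire.

    The summary is the unweighted mean and sample standard deviation across
    donors; donors with zero clonotypes are excluded with a log entry.
    """
    hits = track_all(cells, reps, level)
    queries = unique_queries(cells, level)
    per_donor: dict[str, float] = {}
    for donor in sorted({q.donor_id for q in queries}):
        donor_qs = [q for q in queries if q.donor_id == donor]
        if not donor_qs:
            logger.info("donor %s has zero clonotypes; excluded", donor)
            continue
        n_tracked = 0
        for q in donor_qs:
            qid = q.cdr3b_nt if level == "nt" else q.cdr3b_aa
            m = hits[(hits["query_id"] == qid) & (hits["source_donor"] == donor)]
            if m["found"].any():
                n_tracked += 1
        per_donor[donor] = 100.0 * n_tracked / len(donor_qs)
    vals = np.array(list(per_donor.values()), dtype=float)
    mean = float(vals.mean()) if vals.size else float("nan")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return TrackingRateSummary(per_donor=per_donor, mean=mean, sd=sd)


def treg_cm_ratio(cells: Sequence[ScClonotype], reps: RepertoireSet) -> pd.DataFrame:
    """f_Treg / f_CM for clonotypes found (nt) in both subsets of their source donor.

    Clonotypes absent from either subset of the source donor emit no row.
    """
    rows = []
    for q in unique_queries(cells, "nt"):
        treg = reps.repertoires.get((q.donor_id, "Treg"))
        cm = reps.repertoires.get((q.donor_id, "CM"))
        if treg is None or cm is None:
            continue
        f_treg = treg.nt_frequencies().get(q.cdr3b_nt, 0.0)
        f_cm = cm.nt_frequencies().get(q.cdr3b_nt, 0.0)
        if f_treg == 0.0 or f_cm == 0.0:
            logger.info("clonotype %s absent from Treg or CM of %s; no ratio",
                        q.cdr3b_nt, q.donor_id)
            continue
        rows.append({"donor_id": q.donor_id, "cohort": q.cohort,
                     "cdr3b_nt": q.cdr3b_nt, "f_treg": f_treg, "f_cm": f_cm,
                     "ratio": f_treg / f_cm})
    return pd.DataFrame(rows, columns=["donor_id", "cohort", "cdr3b_nt",
                                       "f_treg", "f_cm", "ratio"])


# ---------------------------------------------------------------------------
# Convergence-frequency correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    subset: str
    group: str
    n: int
    rho: Optional[float]
    p_value: Optional[float]


def convergence_frequency_correlation(hits: pd.DataFrame, subset: str,
                                      group: str = "all",
                                      per_repertoire: bool = False) -> CorrelationResult:
    """Spearman correlation between convergence and peripheral frequency.

    Per clonotype, x is the mean convergence and y the mean frequency across
    the subset's repertoires where it is found (``per_repertoire=True``
    instead uses one point per (clonotype, repertoire) hit).  Requires >= 3
    found clonotypes; identical x ranks leave rho undefined (None).
    """
    sub = hits[(hits["rep_subset"] == subset) & hits["found"]]
    if per_repertoire:
        pts = sub[["convergence", "frequency"]].to_numpy(dtype=float)
    else:
        agg = sub.groupby("query_id", sort=True).agg(
            convergence=("convergence", "mean"), frequency=("frequency", "mean"))
        pts = agg.to_numpy(dtype=float)
    n = pts.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 found clonotypes in {subset}, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    if np.all(x == x[0]):
        return CorrelationResult(subset=subset, group=group, n=n, rho=None, p_value=None)
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(subset=subset, group=group, n=n,
                             rho=float(rho), p_value=float(p))


# ---------------------------------------------------------------------------
# Cohort exclusivity and sequence features
# ---------------------------------------------------------------------------

@dataclass
class ExclusivitySets:
    subset: str
    hd_only: set[str]
    t1d_only: set[str]


def exclusivity_sets(hits: pd.DataFrame, reps: RepertoireSet, subset: str) -> ExclusivitySets:
    """HD-only / T1D-only amino-acid clonotypes for one subset.

    HD-only: found in >= 1 HD repertoire and no T1D repertoire of the subset;
    T1D-only symmetric.  Clonotypes found in both or neither are excluded.
    """
    sub = hits[(hits["rep_subset"] == subset) & hits["found"]]
    hd_only: set[str] = set()
    t1d_only: set[str] = set()
    for qid, grp in sub.groupby("query_id"):
        cohorts = {reps.donor_cohort(d) for d in grp["rep_donor"]}
        if cohorts == {"HD"}:
            hd_only.add(qid)
        elif cohorts == {"T1D"}:
            t1d_only.add(qid)
    return ExclusivitySets(subset=subset, hd_only=hd_only, t1d_only=t1d_only)


AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class SequenceFeatureSummary:
    mean_length: float
    v_usage: dict[str, float]
    positional_frequencies: dict[int, pd.DataFrame]  # length -> 20 x L matrix


def sequence_feature_summary(clonotypes: Sequence[tuple[str, Optional[str]]]) -> SequenceFeatureSummary:
    """CDR3 length / V-gene / positional amino-acid usage for unique clonotypes.

    ``clonotypes`` is a sequence of (cdr3_aa, v_gene) pairs; v_gene may be
    None.  For each CDR3 length represented by >= 2 clonotypes a position x
    amino-acid frequency matrix is built, with each position column summing
    to 1.
    """
    uniq = sorted({(aa, v) for aa, v in clonotypes})
    if not uniq:
        raise ValueError("empty clonotype set")
    seqs = [aa for aa, _ in uniq]
    mean_len = float(np.mean([len(s) for s in seqs]))
    v_genes = [v for _, v in uniq if v]
    v_usage = {}
    if v_genes:
        counts = pd.Series(v_genes).value_counts()
        v_usage = (counts / counts.sum()).sort_index().to_dict()
    pos: dict[int, pd.DataFrame] = {}
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)
    for length, group in sorted(by_len.items()):
        if len(group) < 2:
            continue
        mat = np.zeros((len(AMINO_ACIDS), length))
        aa_idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
        for s in group:
            for j, a in enumerate(s):
                if a in aa_idx:
                    mat[aa_idx[a], j] += 1
        mat /= mat.sum(axis=0, keepdims=True)
        pos[length] = pd.DataFrame(mat, index=list(AMINO_ACIDS),
                                   columns=[f"P{j + 1}" for j in range(length)])
    return SequenceFeatureSummary(mean_length=mean_len, v_usage=v_usage,
                                  positional_frequencies=pos)
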