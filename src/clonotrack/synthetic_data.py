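"""Synthetic tandem single-cell + bulk repertoire generator with planted truth.

Emulates the structure of the study design the analysis modules target:

* 94 bulk TCRB repertoires — 31 donors (17 HD / 14 T1D) each with TN and CM
  subsets, 8 HD + 8 T1D of them additionally with Treg and Tscm;
* antigen-specific single cells from 12 of those donors (5 HD / 7 T1D), a
  configurable number of unique clonotypes per donor, a fixed fraction of
  which is planted into bulk repertoires (the true tracking rate);
* planted publicity (how many donors carry each clonotype, per subset),
  convergence (synonymous nucleotide variants of one amino-acid CDR3),
  cohort exclusivity, and within-donor clonal expansions;
* a single-cell qPCR Ct matrix (48 genes, duplicate wells, censoring at the
  detection ceiling) with known cluster structure, index-sort marker
  intensities on known sides of the phenotype gates, and ELISPOT spot counts.

Background clones are random in-frame, stop-free CDR3 sequences, globally
unique at the nucleotide level and disjoint from every planted amino-acid
clonotype, so the planted structure is the *only* sharing and every planted
quantity is recoverable exactly.  Clone sizes follow a power law; counts are
drawn multinomially at a configurable read depth.  Everything is driven by
one seed; identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genex import CtMatrix, ET_CEILING
from .repertoire_io import (
    BulkRepertoire, Clone, RepertoireSet, ScClonotype,
    PHENOTYPES, translate_cdr3, write_bulk_repertoire, write_sc_clonotypes,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES
                if a + b + c not in _STOPS]
_SYN: dict[str, list[str]] = {}
for codon in SENSE_CODONS:
    _SYN.setdefault(translate_cdr3(codon), []).append(codon)

TRBV_GENES = ["TRBV20-1", "TRBV28", "TRBV29-1", "TRBV6-5", "TRBV19",
              "TRBV5-1", "TRBV7-9", "TRBV9", "TRBV12-3", "TRBV4-1"]
TRBJ_GENES = [f"TRBJ1-{i}" for i in range(1, 7)] + [f"TRBJ2-{i}" for i in range(1, 8)]
TRAV_GENES = ["TRAV12-1", "TRAV8-4", "TRAV29", "TRAV13-1", "TRAV38-2"]
TRAJ_GENES = ["TRAJ23", "TRAJ42", "TRAJ49", "TRAJ33"]

#: 48-gene qPCR panel including the SRP14 housekeeping gene.
GENE_PANEL = (
    "IL4 TBET IL17A RORA CD40 IL13 TGFB CCR3 CXCR5 CCR10 CD52 IFNG TNF GATA3 "
    "IL9 BCL6 RANTES IL17F ICOS IKZF2 IL22 CD4 REL IL18RAP CTLA4 IL10 RGS16 "
    "IL2 AHR MAF CCR6 EGR2 EOMES CD8 GMCSF PD1 CCR7 IL21 CD3E CCR4 GITR RORC "
    "CCR5 FOXP3 NFATC2 CD127 CD134 SRP14"
).split()


@dataclass
class SimConfig:
    """Study-shaped simulation parameters; defaults mirror the emulated design."""

    seed: int = 0
    # bulk cohort layout: 31 TN + 31 CM + 16 Treg + 16 Tscm = 94 repertoires
    n_hd_bulk: int = 17
    n_t1d_bulk: int = 14
    n_hd_tregscm: int = 8
    n_t1d_tregscm: int = 8
    clones_per_repertoire: int = 1000
    reads_per_repertoire: int = 100_000
    power_law_exponent: float = 2.5
    cdr3_nt_lengths: tuple[int, ...] = (36, 39, 42, 45, 48)
    # single-cell arm (5 HD / 7 T1D donors as in the emulated study)
    n_hd_sc: int = 5
    n_t1d_sc: int = 7
    clonotypes_per_donor: int = 10
    tracking_rate: float = 0.2
    alpha_chain_rate: float = 0.5
    # planted structure
    plan_style: str = "default"          # "default" | "monotone"
    n_hd_only: int = 5
    n_t1d_only: int = 4
    exclusive_subset: str = "CM"
    n_expansions: int = 10
    n_confined: int = 3
    expansion_size: int = 3
    # gene expression
    n_clusters: int = 3
    marker_mean_et: float = 10.0
    background_mean_et: float = 1.0
    housekeeping_mean_et: float = 12.0
    et_sd: float = 1.0
    dropout_prob: float = 0.15
    duplicate_missing_rate: float = 0.1
    replicate_ct_sd: float = 0.1
    # assays
    elispot_diluent_mean: float = 10.0
    elispot_positive_mean: float = 50.0
    elispot_negative_mean: float = 12.0
    gate_cutoff: float = 100.0
    marker_positive_logmean: float = math.log(300.0)
    marker_negative_logmean: float = math.log(30.0)
    marker_logsd: float = 0.3

    def __post_init__(self):
        if self.power_law_exponent <= 1:
            raise ValueError("power-law exponent must be > 1")
        if not 0 < self.tracking_rate <= 1:
            raise ValueError("tracking_rate must be in (0, 1]")
        if self.n_hd_sc > self.n_hd_bulk or self.n_t1d_sc > self.n_t1d_bulk:
            raise ValueError("single-cell donors must be a subset of bulk donors")
        if self.n_hd_tregscm > self.n_hd_bulk or self.n_t1d_tregscm > self.n_t1d_bulk:
            raise ValueError("Treg/Tscm donors must be a subset of bulk donors")


@dataclass
class TruthManifest:
    """Exhaustive record of the planted structure, serialisable to JSON."""

    seed: int
    clonotypes: dict = field(default_factory=dict)
    cells: dict = field(default_factory=dict)
    expansions: list = field(default_factory=list)
    donor_tracking_rate_pct: dict = field(default_factory=dict)
    elispot_truth: dict = field(default_factory=dict)
    n_repertoires: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Roster:
    """Donor ids per cohort, their subsets, and the single-cell subset."""

    donors: list[str]
    cohort: dict[str, str]
    subsets: dict[str, list[str]]        # donor -> subsets sequenced
    sc_donors: list[str]

    @classmethod
    def from_config(cls, cfg: SimConfig) -> "Roster":
        hd = [f"HD{i + 1:02d}" for i in range(cfg.n_hd_bulk)]
        t1d = [f"TD{i + 1:02d}" for i in range(cfg.n_t1d_bulk)]
        donors = hd + t1d
        cohort = {d: ("HD" if d.startswith("HD") else "T1D") for d in donors}
        subsets = {d: ["TN", "CM"] for d in donors}
        for d in hd[: cfg.n_hd_tregscm] + t1d[: cfg.n_t1d_tregscm]:
            subsets[d] = ["TN", "CM", "Treg", "Tscm"]
        sc = hd[: cfg.n_hd_sc] + t1d[: cfg.n_t1d_sc]
        return cls(donors=donors, cohort=cohort, subsets=subsets, sc_donors=sc)

    def with_subset(self, subset: str) -> list[str]:
        return [d for d in self.donors if subset in self.subsets[d]]


# ---------------------------------------------------------------------------
# Sequence machinery
# ---------------------------------------------------------------------------

def _random_cdr3_nt(rng: np.random.Generator, lengths: tuple[int, ...]) -> str:
    """Random in-frame, stop-free CDR3 with C...F anchor codons."""
    n_codons = int(rng.choice(lengths)) // 3
    first = ["TGT", "TGC"][int(rng.integers(2))]
    last = ["TTT", "TTC"][int(rng.integers(2))]
    middle = [SENSE_CODONS[int(i)] for i in rng.integers(0, len(SENSE_CODONS),
                                                         size=n_codons - 2)]
    return first + "".join(middle) + last


def _synonymous_variants(base_nt: str, k: int, rng: np.random.Generator) -> list[str]:
    """``k`` distinct nucleotide sequences translating like ``base_nt``.

    The first variant is ``base_nt`` itself; the rest are produced by
    synonymous codon substitutions, translation-checked.
    """
    codons = [base_nt[i:i + 3] for i in range(0, len(base_nt), 3)]
    variants = [base_nt]
    seen = {base_nt}
    guard = 0
    while len(variants) < k:
        guard += 1
        if guard > 1000 * k:
            raise RuntimeError("cannot generate enough synonymous variants")
        new = list(codons)
        n_sub = 1 + int(rng.integers(0, max(1, len(codons) // 3)))
        for pos in rng.choice(len(codons), size=min(n_sub, len(codons)), replace=False):
            aa = translate_cdr3(new[pos])
            new[pos] = _SYN[aa][int(rng.integers(len(_SYN[aa])))]
        cand = "".join(new)
        if cand not in seen:
            assert translate_cdr3(cand) == translate_cdr3(base_nt)
            seen.add(cand)
            variants.append(cand)
    return variants


# ---------------------------------------------------------------------------
# Plan
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """One planted (tracked) clonotype: sequences and seeding plan."""

    clonotype_id: str
    source_donor: str
    template: str
    convergence: int
    count_per_variant: int
    seeds: dict[str, list[str]]          # subset -> donor ids seeded
    aa: str = ""
    variants: list[str] = field(default_factory=list)   # [0] is the cell's nt


def _default_templates(cfg: SimConfig, roster: Roster, rng: np.random.Generator):
    """Cycled template functions mapping a source donor to a seeding plan."""
    tn_donors = roster.with_subset("TN")
    tregscm = roster.with_subset("Treg")

    def pick(pool, n, include=None):
        pool = list(pool)
        chosen = []
        if include is not None and include in pool:
            chosen.append(include)
            pool.remove(include)
        extra = rng.choice(len(pool), size=max(0, n - len(chosen)), replace=False)
        chosen += [pool[int(i)] for i in sorted(extra)]
        return sorted(chosen)

    def tn_extremely_public(src):
        n = max(1, math.ceil(0.77 * len(tn_donors)))
        return {"TN": pick(tn_donors, n, include=src)}, 3, 60

    def tn_public(src):
        n = max(1, round(0.32 * len(tn_donors)))
        return {"TN": pick(tn_donors, n, include=src)}, 2, 50

    def cm_ultraprivate(src):
        return {"CM": [src]}, 1, 40

    def cm_private(src):
        return {"CM": pick(roster.with_subset("CM"), 3, include=src)}, 2, 50

    def treg_cm(src):
        if "Treg" in roster.subsets[src]:
            return {"Treg": [src], "CM": [src]}, 1, 80
        return cm_private(src)

    def tscm_private(src):
        target = src if "Tscm" in roster.subsets[src] else tregscm[0]
        return {"Tscm": [target]}, 1, 40

    return [tn_extremely_public, tn_public, cm_ultraprivate, cm_private,
            treg_cm, tscm_private]


def build_plan(cfg: SimConfig, roster: Roster, rng: np.random.Generator) -> list[PlantSpec]:
    """Assign each single-cell donor its tracked clonotypes' seeding plans."""
    n_tracked = max(1, round(cfg.tracking_rate * cfg.clonotypes_per_donor))
    slots = [(d, i) for d in roster.sc_donors for i in range(n_tracked)]
    specs: list[PlantSpec] = []

    if cfg.plan_style == "monotone":
        # strictly monotone convergence -> frequency relation in TN
        anchor_reps = roster.with_subset("TN")[:5]
        for j, (donor, i) in enumerate(slots, start=1):
            specs.append(PlantSpec(
                clonotype_id=f"{donor}_t{i}", source_donor=donor,
                template="monotone", convergence=j, count_per_variant=10 * j,
                seeds={"TN": list(anchor_reps)},
            ))
        return specs

    templates = _default_templates(cfg, roster, rng)
    hd_pool = [d for d in roster.donors if roster.cohort[d] == "HD"
               and cfg.exclusive_subset in roster.subsets[d]]
    t1d_pool = [d for d in roster.donors if roster.cohort[d] == "T1D"
                and cfg.exclusive_subset in roster.subsets[d]]
    cycle = 0
    for j, (donor, i) in enumerate(slots):
        if j < cfg.n_hd_only:
            n_seed = min(2 + j % 3, len(hd_pool))
            idx = rng.choice(len(hd_pool), size=n_seed, replace=False)
            seeds = {cfg.exclusive_subset: sorted(hd_pool[int(x)] for x in sorted(idx))}
            template, k, count = "hd_only", 1 + j % 2, 50
        elif j < cfg.n_hd_only + cfg.n_t1d_only:
            n_seed = min(2 + j % 3, len(t1d_pool))
            idx = rng.choice(len(t1d_pool), size=n_seed, replace=False)
            seeds = {cfg.exclusive_subset: sorted(t1d_pool[int(x)] for x in sorted(idx))}
            template, k, count = "t1d_only", 1 + j % 2, 50
        else:
            fn = templates[cycle % len(templates)]
            cycle += 1
            seeds, k, count = fn(donor)
            template = fn.__name__
        specs.append(PlantSpec(
            clonotype_id=f"{donor}_t{i}", source_donor=donor, template=template,
            convergence=k, count_per_variant=count, seeds=seeds,
        ))
    return specs


# ---------------------------------------------------------------------------
# Bulk simulation
# ---------------------------------------------------------------------------

def simulate_bulk(cfg: SimConfig) -> tuple[RepertoireSet, TruthManifest]:
    """Generate the 94-repertoire bulk set with the planted clonotypes.

    The returned manifest records, per planted clonotype, the seeded donors,
    convergence, realised frequencies, publicity category per subset and the
    cohort-exclusivity label derived from the seeding.
    """
    roster = Roster.from_config(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng_plan, rng_seq, rng_bulk, _, _ = [np.random.default_rng(c)
                                         for c in ss.spawn(5)]
    plan = build_plan(cfg, roster, rng_plan)

    # planted sequences, unique at nucleotide and amino-acid level
    global_nt: set[str] = set()
    planted_aa: set[str] = set()
    for spec in plan:
        while True:
            base = _random_cdr3_nt(rng_seq, cfg.cdr3_nt_lengths)
            aa = translate_cdr3(base)
            if base not in global_nt and aa not in planted_aa:
                break
        spec.variants = _synonymous_variants(base, spec.convergence, rng_seq)
        spec.aa = aa
        planted_aa.add(aa)
        global_nt.update(spec.variants)

    # per-repertoire planted injections
    injections: dict[tuple[str, str], list[tuple[PlantSpec, str]]] = {}
    for spec in plan:
        for subset, donors in spec.seeds.items():
            for d in donors:
                for nt in spec.variants:
                    injections.setdefault((d, subset), []).append((spec, nt))

    reps = RepertoireSet()
    manifest = TruthManifest(seed=cfg.seed)
    for donor in roster.donors:
        for subset in roster.subsets[donor]:
            rep = _simulate_repertoire(cfg, donor, roster.cohort[donor], subset,
                                       injections.get((donor, subset), []),
                                       global_nt, planted_aa, rng_bulk)
            reps.add(rep)
    manifest.n_repertoires = reps.subset_counts()

    # realised frequencies + derived truth
    for spec in plan:
        freqs: dict[str, dict[str, float]] = {}
        for subset, donors in spec.seeds.items():
            for d in donors:
                rep = reps.repertoires[(d, subset)]
                nt_f = rep.nt_frequencies()
                variant_f = [nt_f[v] for v in spec.variants]
                freqs[f"{d}|{subset}"] = {
                    "nt": variant_f[0],
                    "aa": float(np.mean(variant_f)),
                }
        publicity = {}
        exclusivity = {}
        for subset, donors in spec.seeds.items():
            n_searched = manifest.n_repertoires[subset]
            n_found = len(donors)
            pct = 100.0 * n_found / n_searched
            source_only = set(donors) <= {spec.source_donor}
            if pct >= 75.0:
                cat = "extremely_public"
            elif pct >= 25.0:
                cat = "public"
            elif n_found == 1 and source_only:
                cat = "ultraprivate"
            else:
                cat = "private"
            publicity[subset] = {"n_found": n_found, "n_searched": n_searched,
                                 "pct": pct, "category": cat}
            cohorts = {roster.cohort[d] for d in donors}
            exclusivity[subset] = ("HD_only" if cohorts == {"HD"}
                                   else "T1D_only" if cohorts == {"T1D"}
                                   else "shared")
        manifest.clonotypes[spec.clonotype_id] = {
            "aa": spec.aa, "nt": spec.variants[0], "variants": list(spec.variants),
            "source_donor": spec.source_donor, "template": spec.template,
            "convergence": spec.convergence,
            "seeds": {s: list(d) for s, d in spec.seeds.items()},
            "frequencies": freqs, "publicity": publicity,
            "exclusivity": exclusivity,
        }
    return reps, manifest


def _simulate_repertoire(cfg, donor, cohort, subset, injected, global_nt,
                         planted_aa, rng) -> BulkRepertoire:
    n = cfg.clones_per_repertoire
    # power-law clone sizes as multinomial weights (Pareto tail index a-1)
    u = rng.random(n)
    sizes = np.ceil(u ** (-1.0 / (cfg.power_law_exponent - 1.0)))
    sizes = np.minimum(sizes, cfg.reads_per_repertoire / 10.0)
    counts = rng.multinomial(cfg.reads_per_repertoire, sizes / sizes.sum())

    lengths = np.asarray(cfg.cdr3_nt_lengths)
    n_codon_choices = rng.integers(0, len(lengths), size=n)
    clones: list[Clone] = []
    for i in range(n):
        if counts[i] == 0:
            continue
        while True:
            n_codons = int(lengths[n_codon_choices[i]]) // 3
            first = ["TGT", "TGC"][int(rng.integers(2))]
            last = ["TTT", "TTC"][int(rng.integers(2))]
            mid = rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)
            nt = first + "".join(SENSE_CODONS[int(j)] for j in mid) + last
            aa = translate_cdr3(nt)
            if nt not in global_nt and aa not in planted_aa:
                break
        global_nt.add(nt)
        clones.append(Clone(
            cdr3_nt=nt, cdr3_aa=aa,
            v_call=TRBV_GENES[int(rng.integers(len(TRBV_GENES)))],
            j_call=TRBJ_GENES[int(rng.integers(len(TRBJ_GENES)))],
            count=int(counts[i]),
        ))
    for spec, nt in injected:
        clones.append(Clone(
            cdr3_nt=nt, cdr3_aa=spec.aa,
            v_call=TRBV_GENES[int(rng.integers(len(TRBV_GENES)))],
            j_call=TRBJ_GENES[int(rng.integers(len(TRBJ_GENES)))],
            count=spec.count_per_variant,
        ))
    return BulkRepertoire(donor_id=donor, cohort=cohort, subset=subset, clones=clones)


# ---------------------------------------------------------------------------
# Single-cell simulation
# ---------------------------------------------------------------------------

def simulate_sc(cfg: SimConfig, reps: RepertoireSet, manifest: TruthManifest
                ) -> tuple[list[ScClonotype], CtMatrix, pd.DataFrame, TruthManifest]:
    """Emit single cells, the Ct matrix and index-sort marker intensities.

    Tracked clonotypes come from the bulk plan in the manifest; the rest are
    de novo sequences absent from every repertoire, which fixes each donor's
    true tracking rate.  Expansions, cluster identities, phenotypes and Ct
    values are planted and recorded.
    """
    roster = Roster.from_config(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    _, _, _, rng_sc, _ = [np.random.default_rng(c) for c in ss.spawn(5)]

    bulk_nt = {c.cdr3_nt for rep in reps for c in rep.clones}
    bulk_aa = {c.cdr3_aa for rep in reps for c in rep.clones}

    tracked_by_donor: dict[str, list[dict]] = {}
    for cid, rec in sorted(manifest.clonotypes.items()):
        tracked_by_donor.setdefault(rec["source_donor"], []).append(dict(rec, id=cid))

    n_tracked = max(1, round(cfg.tracking_rate * cfg.clonotypes_per_donor))
    cells: list[ScClonotype] = []
    expansion_slots = list(range(cfg.n_expansions))
    expansion_assignment = {
        roster.sc_donors[i % len(roster.sc_donors)]: []
        for i in expansion_slots
    }
    for i in expansion_slots:
        expansion_assignment[roster.sc_donors[i % len(roster.sc_donors)]].append(i)

    used_aa: set[str] = set(bulk_aa)
    cell_counter = 0
    cluster_cycle = 0
    for donor in roster.sc_donors:
        cohort = roster.cohort[donor]
        clonotypes: list[dict] = []
        for rec in tracked_by_donor.get(donor, []):
            clonotypes.append({"nt": rec["nt"], "aa": rec["aa"], "tracked": True,
                               "id": rec["id"]})
        n_denovo = cfg.clonotypes_per_donor - len(clonotypes)
        for i in range(n_denovo):
            while True:
                nt = _random_cdr3_nt(rng_sc, cfg.cdr3_nt_lengths)
                aa = translate_cdr3(nt)
                if nt not in bulk_nt and aa not in used_aa:
                    break
            used_aa.add(aa)
            clonotypes.append({"nt": nt, "aa": aa, "tracked": False,
                               "id": f"{donor}_d{i}"})

        # alpha chains, shared within a clonotype
        for ct in clonotypes:
            if rng_sc.random() < cfg.alpha_chain_rate:
                ct["alpha_nt"] = _random_cdr3_nt(rng_sc, cfg.cdr3_nt_lengths)
            else:
                ct["alpha_nt"] = None
            ct["v"] = TRBV_GENES[int(rng_sc.integers(len(TRBV_GENES)))]
            ct["j"] = TRBJ_GENES[int(rng_sc.integers(len(TRBJ_GENES)))]

        # expansions live on de-novo clonotypes so bulk seeding stays untouched
        denovo = [c for c in clonotypes if not c["tracked"]]
        groups = expansion_assignment.get(donor, []) if denovo else []
        expansion_hosts = {}
        for slot_idx, g in enumerate(groups):
            host = denovo[slot_idx % len(denovo)]
            expansion_hosts[host["id"]] = g

        for ct in clonotypes:
            if ct["id"] in expansion_hosts:
                g = expansion_hosts[ct["id"]]
                size = cfg.expansion_size
                confined = g < cfg.n_confined
                if confined:
                    clusters = [g % cfg.n_clusters + 1] * size
                else:
                    clusters = [(g + m) % cfg.n_clusters + 1 for m in range(size)]
                    if len(set(clusters)) == 1:  # guard tiny n_clusters
                        clusters[-1] = clusters[-1] % cfg.n_clusters + 1
                member_ids = []
                for m in range(size):
                    cell_counter += 1
                    member_ids.append(f"{donor}_c{cell_counter:04d}")
                manifest.expansions.append({
                    "donor": donor, "cdr3b_nt": ct["nt"], "cell_ids": member_ids,
                    "confined": bool(confined),
                    "clusters": sorted(set(clusters)),
                })
                for cid, cl in zip(member_ids, clusters):
                    _emit_cell(cfg, manifest, cells, cid, donor, cohort, ct, cl,
                               rng_sc, cluster_cycle)
                    cluster_cycle += 1
            else:
                cell_counter += 1
                cid = f"{donor}_c{cell_counter:04d}"
                cl = cluster_cycle % cfg.n_clusters + 1
                _emit_cell(cfg, manifest, cells, cid, donor, cohort, ct, cl,
                           rng_sc, cluster_cycle)
                cluster_cycle += 1
        manifest.donor_tracking_rate_pct[donor] = (
            100.0 * sum(1 for c in clonotypes if c["tracked"]) / len(clonotypes)
        )

    ct_matrix, markers = _simulate_expression(cfg, manifest, cells, rng_sc)
    return cells, ct_matrix, markers, manifest


def _emit_cell(cfg, manifest, cells, cell_id, donor, cohort, ct, cluster,
               rng, cycle) -> None:
    phenotype = PHENOTYPES[cycle % len(PHENOTYPES)]
    cells.append(ScClonotype(
        cell_id=cell_id, donor_id=donor, cohort=cohort, specificity="GAD",
        cdr3b_nt=ct["nt"], cdr3b_aa=ct["aa"], v_gene_b=ct["v"], j_gene_b=ct["j"],
        cdr3a_nt=ct["alpha_nt"],
        cdr3a_aa=translate_cdr3(ct["alpha_nt"]) if ct["alpha_nt"] else None,
        phenotype=phenotype, genex_cluster=cluster,
    ))
    manifest.cells[cell_id] = {
        "clonotype_id": ct["id"], "donor": donor, "cohort": cohort,
        "true_cluster": int(cluster), "phenotype": phenotype,
        "tracked": bool(ct["tracked"]),
    }


def cluster_mean_matrix(cfg: SimConfig) -> pd.DataFrame:
    """Per-cluster gene mean Et: one 8-gene marker block per cluster."""
    genes = GENE_PANEL
    m = np.full((cfg.n_clusters, len(genes)), cfg.background_mean_et)
    block = 8
    for c in range(cfg.n_clusters):
        lo = (c * block) % (len(genes) - 1)
        m[c, lo:lo + block] = cfg.marker_mean_et
    m[:, genes.index("SRP14")] = cfg.housekeeping_mean_et
    return pd.DataFrame(m, index=range(1, cfg.n_clusters + 1), columns=genes)


def _simulate_expression(cfg, manifest, cells, rng) -> tuple[CtMatrix, pd.DataFrame]:
    means = cluster_mean_matrix(cfg)
    ct_rows = []
    marker_rows = []
    for cell in cells:
        truth = manifest.cells[cell.cell_id]
        mu = means.loc[truth["true_cluster"]].to_numpy()
        et = rng.normal(mu, cfg.et_sd)
        et = np.clip(et, 0.0, ET_CEILING)
        dropped = rng.random(et.size) < cfg.dropout_prob
        et[dropped] = 0.0
        for g, gene in enumerate(GENE_PANEL):
            if et[g] <= 0:
                ct1 = ct2 = np.nan
            else:
                ct_true = ET_CEILING - et[g]
                ct1 = max(ct_true + rng.normal(0, cfg.replicate_ct_sd), 1e-3)
                ct2 = max(ct_true + rng.normal(0, cfg.replicate_ct_sd), 1e-3)
                if rng.random() < cfg.duplicate_missing_rate:
                    ct2 = np.nan
            ct_rows.append((cell.cell_id, gene, 1, ct1))
            ct_rows.append((cell.cell_id, gene, 2, ct2))
        marker_rows.append(_marker_intensities(cfg, cell, rng))
    ct_df = pd.DataFrame(ct_rows, columns=["cell_id", "gene", "replicate", "ct"])
    meta = pd.DataFrame(
        [{"cell_id": c.cell_id, "donor_id": c.donor_id, "cohort": c.cohort,
          "phenotype": c.phenotype} for c in cells]
    ).set_index("cell_id")
    markers = pd.DataFrame(marker_rows)
    return CtMatrix(ct=ct_df, cell_meta=meta), markers


_PHENOTYPE_MARKER_TRUTH = {
    # phenotype -> (CD45RO+, CD27+, CD95+)
    "TN": (False, True, False),
    "CM": (True, True, False),
    "EM": (True, False, False),
    "NTEM": (False, False, False),
    "Tscm": (False, True, True),
}


def _marker_intensities(cfg, cell, rng) -> dict:
    ro, cd27, cd95 = _PHENOTYPE_MARKER_TRUTH[cell.phenotype]

    def draw(pos: bool) -> float:
        mu = cfg.marker_positive_logmean if pos else cfg.marker_negative_logmean
        return float(np.exp(rng.normal(mu, cfg.marker_logsd)))

    return {
        "cell_id": cell.cell_id, "donor_id": cell.donor_id, "cohort": cell.cohort,
        "CD45RO": draw(ro), "CD27": draw(cd27), "CD95": draw(cd95),
        "CD154": draw(True), "CD69": draw(True),
        "gate_CD45RO": cfg.gate_cutoff, "gate_CD27": cfg.gate_cutoff,
        "gate_CD95": cfg.gate_cutoff,
    }


# ---------------------------------------------------------------------------
# Assays
# ---------------------------------------------------------------------------

ELISPOT_CLASSES = ("negative", "IFNg_only", "IL10_only", "dual")


def simulate_assays(cfg: SimConfig, manifest: TruthManifest) -> pd.DataFrame:
    """Triplicate ELISPOT spot counts per donor x cytokine, Poisson noise.

    Donors cycle through the four response classes; the planted class is
    recorded in the manifest (recovery is Monte-Carlo, not exact: a Poisson
    draw near the SI = 3 boundary can flip).
    """
    roster = Roster.from_config(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(5)[4])
    rows = []
    for i, donor in enumerate(roster.donors):
        truth = ELISPOT_CLASSES[i % len(ELISPOT_CLASSES)]
        manifest.elispot_truth[donor] = truth
        for cytokine in ("IFNg", "IL10"):
            pos = (truth == "dual" or truth == f"{cytokine}_only")
            ag_mean = cfg.elispot_positive_mean if pos else cfg.elispot_negative_mean
            ag = rng.poisson(ag_mean, size=3)
            dil = rng.poisson(cfg.elispot_diluent_mean, size=3)
            rows.append({
                "donor_id": donor, "cohort": roster.cohort[donor],
                "cytokine": cytokine,
                "antigen_1": ag[0], "antigen_2": ag[1], "antigen_3": ag[2],
                "diluent_1": dil[0], "diluent_2": dil[1], "diluent_3": dil[2],
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration and serialisation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    cfg: SimConfig
    reps: RepertoireSet
    cells: list[ScClonotype]
    ct: CtMatrix
    markers: pd.DataFrame
    elispot: pd.DataFrame
    manifest: TruthManifest


def simulate_all(cfg: SimConfig) -> SimResult:
    """Run bulk, single-cell and assay generation under one seed."""
    reps, manifest = simulate_bulk(cfg)
    cells, ct, markers, manifest = simulate_sc(cfg, reps, manifest)
    elispot = simulate_assays(cfg, manifest)
    return SimResult(cfg=cfg, reps=reps, cells=cells, ct=ct, markers=markers,
                     elispot=elispot, manifest=manifest)


def write_sim(result: SimResult, outdir) -> None:
    """Write AIRR TSVs, cell/Ct/assay tables and the truth manifest."""
    out = Path(outdir)
    (out / "repertoires").mkdir(parents=True, exist_ok=True)
    for (donor, subset), rep in sorted(result.reps.repertoires.items()):
        write_bulk_repertoire(rep, out / "repertoires" / f"{donor}_{subset}.tsv")
    write_sc_clonotypes(result.cells, out / "cells.tsv")
    result.ct.ct.to_csv(out / "ct.tsv", sep="\t", index=False, lineterminator="\n",
                        float_format="%.6f")
    result.markers.to_csv(out / "aim_markers.tsv", sep="\t", index=False,
                          lineterminator="\n", float_format="%.6f")
    result.elispot.to_csv(out / "elispot.tsv", sep="\t", index=False,
                          lineterminator="\n")
    result.manifest.to_json(out / "manifest.json")
    cohorts = sorted({(d, result.reps.donor_cohort(d))
                      for d, _ in result.reps.repertoires})
    pd.DataFrame(cohorts, columns=["donor_id", "cohort"]).to_csv(
        out / "donors.tsv", sep="\t", index=False, lineterminator="\n")


def read_repertoire_dir(path, donors_tsv=None) -> RepertoireSet:
    """Load a directory of ``{donor}_{subset}.tsv`` AIRR files."""
    from .repertoire_io import read_bulk_repertoire

    path = Path(path)
    cohorts = {}
    donors_file = Path(donors_tsv) if donors_tsv else path.parent / "donors.tsv"
    if donors_file.exists():
        df = pd.read_csv(donors_file, sep="\t", dtype=str)
        cohorts = dict(zip(df["donor_id"], df["cohort"]))
    reps = RepertoireSet()
    for f in sorted(path.glob("*.tsv")):
        donor, subset = f.stem.rsplit("_", 1)
        cohort = cohorts.get(donor, "HD" if donor.startswith("HD") else "T1D")
        reps.add(read_bulk_repertoire(f, donor_id=donor, cohort=cohort, subset=subset))
    return reps
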