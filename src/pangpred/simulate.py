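"""Synthetic pan-genome panel: structured genotypes, dispensable vertices
and additive phenotypes.

The generator emulates the statistical structure of a gene bank panel mapped
against a pan-genome graph:

* **Population structure** — K subpopulations under the Balding-Nichols
  model: each SNP has an ancestral frequency ~ Uniform(0.05, 0.95) and
  subpopulation frequencies ~ Beta with mean p and variance p(1-p)*Fst.
  Accessions are near-fully inbred diploids (hom-alt with probability f,
  hom-ref otherwise) with a small fraction of calls flipped to heterozygous
  to emulate residual heterozygosity.
* **Dispensable vertices** — each vertex has a home subpopulation and a
  source reference with a graph build rank; per accession, the vertex
  segment is present with probability ``p_home`` (home) or ``p_away``
  (away).  SNPs nested in an absent segment are missing by construction;
  uniform technical missingness is layered on all calls, making technical
  and biological missingness indistinguishable in the observed data.
* **Phenotype** — additive breeding values from three effect classes (core
  SNP dosages, vertex presence, within-vertex SNP dosages for present
  accessions), plus Gaussian noise scaled to a target heritability.

All outputs are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotypes import Call, GenotypeCalls, SnpRecord, VertexRecord

__all__ = [
    "SimConfig",
    "PopulationSim",
    "VertexSim",
    "SimTruth",
    "SimData",
    "simulate_population",
    "simulate_vertices",
    "simulate_phenotype",
    "simulate_panel",
]

_NUC = np.array(list("ACGT"))

BACKBONE = "NB"


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.

    Defaults describe a three-subpopulation panel of 600 inbred accessions
    with strong subpopulation enrichment of vertex presence (the regime in
    which call-rate structure is clearly visible).  ``h2`` is narrow-sense
    heritability of the simulated trait; effect scales are standard
    deviations of the Normal effect-size draws per class.
    """

    subpop_sizes: tuple[tuple[str, int], ...] = (
        ("aus", 200), ("indica", 200), ("japonica", 200)
    )
    fst: float = 0.3
    n_core_snps: int = 3000
    n_vertices: int = 150
    snps_per_vertex: tuple[int, int] = (2, 8)  # inclusive range
    vertex_size_bp: tuple[int, int] = (2000, 20000)  # straddles the 5 kb cut
    refs_per_subpop: int = 1
    p_home: float = 0.9
    p_away: float = 0.2
    tech_missing_rate: float = 0.05
    selfing_het_rate: float = 0.02
    n_causal_core: int = 100
    core_effect_scale: float = 1.0
    n_causal_presence: int = 40
    presence_effect_scale: float = 3.2
    n_causal_vertex_snps: int = 20
    vertex_snp_effect_scale: float = 1.0
    causal_vertex_min_bp: int = 5000
    h2: float = 0.5
    trait_name: str = "sim_trait"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_home", "p_away", "selfing_het_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.tech_missing_rate < 1.0):
            raise ValueError("tech_missing_rate must lie in [0, 1)")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must lie in (0, 1)")
        if not (0.0 < self.h2 <= 1.0):
            raise ValueError("h2 must lie in (0, 1]")
        if self.n_causal_presence > 0 and not self.p_home > self.p_away:
            raise ValueError("enriched vertices require p_home > p_away")

    @property
    def n_accessions(self) -> int:
        return sum(n for _, n in self.subpop_sizes)

    @property
    def subpop_labels(self) -> list[str]:
        return [lab for lab, _ in self.subpop_sizes]


@dataclass
class PopulationSim:
    """Core-genome simulation output."""

    calls: GenotypeCalls  # observed (with technical missingness)
    true_dosage: np.ndarray  # pre-missingness 0/1/2 dosages
    subpops: pd.Series
    ancestral_freq: np.ndarray
    subpop_freq: pd.DataFrame  # subpop x SNP alt-allele frequencies


@dataclass
class VertexSim:
    """Dispensable-genome simulation output."""

    vertices: list[VertexRecord]
    presence: pd.DataFrame  # accessions x vertex_id, boolean
    calls: GenotypeCalls  # observed vertex-SNP calls (absent -> missing)
    true_dosage: np.ndarray  # nucleotide dosage for present accessions, 0 where absent
    vertex_by_snp: dict[str, str]
    home_subpop: dict[str, str]  # vertex_id -> home subpopulation
    reference_ranks: dict[str, int]


@dataclass
class SimTruth:
    """Ground truth of the phenotype simulation."""

    breeding_values: pd.Series
    causal_core: pd.Series  # snp_id -> effect
    causal_presence: pd.Series  # vertex_id -> effect
    causal_vertex_snps: pd.Series  # snp_id -> effect
    var_components: dict[str, float]  # realized variance per effect class
    realized_h2: float
    sigma2_e: float


@dataclass
class SimData:
    """Full panel bundle as the pipeline consumes it."""

    config: SimConfig
    calls_by_reference: dict[str, GenotypeCalls]
    vertices: list[VertexRecord]
    reference_ranks: dict[str, int]
    phenotypes: pd.DataFrame
    subpops: pd.Series
    population: PopulationSim
    vertex_sim: VertexSim
    truth: SimTruth


def _draw_inbred_calls(
    freqs: np.ndarray,
    subpop_idx: np.ndarray,
    het_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Near-inbred diploid dosages: hom-alt w.p. f, else hom-ref, then a
    ``het_rate`` fraction of calls flipped to heterozygous."""
    n, m = subpop_idx.shape[0], freqs.shape[1]
    f = freqs[subpop_idx, :]  # n x m
    g = np.where(rng.random((n, m)) < f, 2, 0).astype(np.int8)
    if het_rate > 0:
        g[rng.random((n, m)) < het_rate] = 1
    return g


def _subpop_frequencies(
    ancestral: np.ndarray, n_subpops: int, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols: Beta(p(1-F)/F, (1-p)(1-F)/F) per subpopulation."""
    a = ancestral * (1.0 - fst) / fst
    b = (1.0 - ancestral) * (1.0 - fst) / fst
    return rng.beta(a, b, size=(n_subpops, ancestral.shape[0]))


def _apply_missing(g: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = g.copy()
    if rate > 0:
        out[rng.random(g.shape) < rate] = Call.MISSING
    return out


def _accession_ids(config: SimConfig) -> tuple[list[str], np.ndarray, pd.Series]:
    ids: list[str] = []
    subpop_idx: list[int] = []
    labels: list[str] = []
    for k, (lab, n) in enumerate(config.subpop_sizes):
        for i in range(n):
            ids.append(f"{lab}_{i:04d}")
            subpop_idx.append(k)
            labels.append(lab)
    subpops = pd.Series(labels, index=pd.Index(ids, name="accession_id"),
                        name="subpopulation")
    return ids, np.array(subpop_idx), subpops


def simulate_population(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> PopulationSim:
    """Simulate core-genome SNP calls on the backbone reference."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ids, subpop_idx, subpops = _accession_ids(config)
    m = config.n_core_snps
    ancestral = rng.uniform(0.05, 0.95, size=m)
    freqs = _subpop_frequencies(ancestral, len(config.subpop_sizes), config.fst, rng)
    true = _draw_inbred_calls(freqs, subpop_idx, config.selfing_het_rate, rng)
    observed = _apply_missing(true, config.tech_missing_rate, rng)

    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    snps = [
        SnpRecord(
            snp_id=f"core{j:05d}",
            source_reference=BACKBONE,
            chromosome="chr1",
            position=(j + 1) * 100,
            ref_allele=_NUC[ref_idx[j]],
            alt_allele=_NUC[(ref_idx[j] + alt_shift[j]) % 4],
        )
        for j in range(m)
    ]
    calls = GenotypeCalls(ids, snps, observed)
    return PopulationSim(
        calls=calls,
        true_dosage=true.astype(float),
        subpops=subpops,
        ancestral_freq=ancestral,
        subpop_freq=pd.DataFrame(freqs, index=config.subpop_labels),
    )


def simulate_vertices(
    config: SimConfig,
    subpops: pd.Series,
    rng: Optional[np.random.Generator] = None,
) -> VertexSim:
    """Simulate dispensable vertices, their presence pattern and nested SNPs.

    References are named ``REF_<subpop>[_i]`` with ranks following their
    creation order; the backbone itself never sources a vertex.  Vertex
    sizes are drawn uniformly from the configured range, so some vertices
    fall below the 5 kb selection cut on purpose.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    labels = list(subpops)
    label_names = config.subpop_labels
    subpop_idx = np.array([label_names.index(l) for l in labels])
    ids = list(subpops.index)
    n = len(ids)

    references: list[tuple[str, str]] = []  # (ref name, home subpop)
    for i in range(config.refs_per_subpop):
        for lab in label_names:
            name = f"REF_{lab}" if config.refs_per_subpop == 1 else f"REF_{lab}_{i}"
            references.append((name, lab))
    reference_ranks = {name: r + 1 for r, (name, _) in enumerate(references)}

    lo_s, hi_s = config.snps_per_vertex
    lo_b, hi_b = config.vertex_size_bp
    vertices: list[VertexRecord] = []
    home: dict[str, str] = {}
    presence_cols: list[np.ndarray] = []
    snps: list[SnpRecord] = []
    true_cols: list[np.ndarray] = []
    obs_cols: list[np.ndarray] = []
    vertex_by_snp: dict[str, str] = {}
    cursor = {name: 0 for name, _ in references}

    for v in range(config.n_vertices):
        ref_name, ref_home = references[v % len(references)]
        vid = f"vx{v:04d}"
        size = int(rng.integers(lo_b, hi_b + 1))
        start = cursor[ref_name]
        end = start + size
        cursor[ref_name] = end + 1000  # gap so vertices never overlap
        vertices.append(
            VertexRecord(vid, ref_name, "chr1", start, end, rank=reference_ranks[ref_name])
        )
        home[vid] = ref_home

        p = np.where(np.array(labels) == ref_home, config.p_home, config.p_away)
        present = rng.random(n) < p
        presence_cols.append(present)

        n_snps = int(rng.integers(lo_s, hi_s + 1))
        positions = np.sort(rng.choice(np.arange(start + 1, end + 1), size=n_snps,
                                       replace=False))
        ancestral = rng.uniform(0.05, 0.95, size=n_snps)
        freqs = _subpop_frequencies(ancestral, len(label_names), config.fst, rng)
        g_true = _draw_inbred_calls(freqs, subpop_idx, config.selfing_het_rate, rng)
        g_obs = g_true.copy()
        g_obs[~present, :] = Call.MISSING  # biological absence
        g_obs = _apply_missing(g_obs, config.tech_missing_rate, rng)
        # nucleotide dosage contributes only where the segment is present
        g_dose = g_true.astype(float)
        g_dose[~present, :] = 0.0

        ref_idx = rng.integers(0, 4, size=n_snps)
        alt_shift = rng.integers(1, 4, size=n_snps)
        for j in range(n_snps):
            sid = f"{vid}_s{j:02d}"
            snps.append(
                SnpRecord(
                    snp_id=sid,
                    source_reference=ref_name,
                    chromosome="chr1",
                    position=int(positions[j]),
                    ref_allele=_NUC[ref_idx[j]],
                    alt_allele=_NUC[(ref_idx[j] + alt_shift[j]) % 4],
                )
            )
            vertex_by_snp[sid] = vid
        true_cols.append(g_dose)
        obs_cols.append(g_obs)

    presence = pd.DataFrame(
        np.column_stack(presence_cols) if presence_cols else np.empty((n, 0), dtype=bool),
        index=pd.Index(ids, name="accession_id"),
        columns=[v.vertex_id for v in vertices],
    )
    calls = GenotypeCalls(
        ids, snps,
        np.hstack(obs_cols) if obs_cols else np.empty((n, 0), dtype=np.int8),
    )
    true_dosage = (
        np.hstack(true_cols) if true_cols else np.empty((n, 0), dtype=float)
    )
    return VertexSim(
        vertices=vertices,
        presence=presence,
        calls=calls,
        true_dosage=true_dosage,
        vertex_by_snp=vertex_by_snp,
        home_subpop=home,
        reference_ranks=reference_ranks,
    )


def simulate_phenotype(
    population: PopulationSim,
    vertex_sim: VertexSim,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive phenotype from core dosages, vertex presence and vertex SNPs.

    Breeding values use the *true* (pre-missingness) genotypes; the analysis
    only ever sees the observed calls.  Causal vertices are drawn among
    vertices large enough to pass the dispensable-genome size cut, since
    those segments are the analysis target.  Environmental noise is scaled
    so that Var(g) / (Var(g) + sigma2_e) equals the target heritability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ids = population.calls.accession_ids
    n = len(ids)
    g = np.zeros(n)
    var_components: dict[str, float] = {}

    core_ids = population.calls.snp_ids
    n_core_causal = min(config.n_causal_core, len(core_ids))
    causal_core = pd.Series(dtype=float)
    if n_core_causal > 0:
        pick = rng.choice(len(core_ids), size=n_core_causal, replace=False)
        effects = rng.normal(0.0, config.core_effect_scale, size=n_core_causal)
        contrib = population.true_dosage[:, pick] @ effects
        g = g + contrib
        var_components["core"] = float(np.var(contrib))
        causal_core = pd.Series(effects, index=[core_ids[j] for j in pick])

    big = [v.vertex_id for v in vertex_sim.vertices
           if v.size_bp > config.causal_vertex_min_bp]
    n_pres = min(config.n_causal_presence, len(big))
    causal_presence = pd.Series(dtype=float)
    if n_pres > 0:
        pick_v = [str(v) for v in rng.choice(big, size=n_pres, replace=False)]
        effects = rng.normal(0.0, config.presence_effect_scale, size=n_pres)
        contrib = vertex_sim.presence[pick_v].to_numpy(float) @ effects
        g = g + contrib
        var_components["presence"] = float(np.var(contrib))
        causal_presence = pd.Series(effects, index=pick_v)

    vx_snp_ids = vertex_sim.calls.snp_ids
    big_set = set(big)
    in_big = [j for j, sid in enumerate(vx_snp_ids)
              if vertex_sim.vertex_by_snp[sid] in big_set]
    n_vx = min(config.n_causal_vertex_snps, len(in_big))
    causal_vx = pd.Series(dtype=float)
    if n_vx > 0:
        pick = rng.choice(in_big, size=n_vx, replace=False)
        effects = rng.normal(0.0, config.vertex_snp_effect_scale, size=n_vx)
        contrib = vertex_sim.true_dosage[:, pick] @ effects
        g = g + contrib
        var_components["vertex_snp"] = float(np.var(contrib))
        causal_vx = pd.Series(effects, index=[vx_snp_ids[j] for j in pick])

    var_g = float(np.var(g))
    if var_g == 0.0:
        if config.h2 > 0 and (n_core_causal + n_pres + n_vx) > 0:
            raise ValueError("zero genetic variance with h2 > 0")
        sigma2_e = 1.0
    else:
        sigma2_e = var_g * (1.0 - config.h2) / config.h2
    noise = rng.normal(0.0, np.sqrt(sigma2_e), size=n) if sigma2_e > 0 else np.zeros(n)
    y = g + noise
    tot = float(np.var(y))
    realized_h2 = var_g / tot if tot > 0 else 0.0

    phenotypes = pd.DataFrame(
        {config.trait_name: y}, index=pd.Index(ids, name="accession_id")
    )
    truth = SimTruth(
        breeding_values=pd.Series(g, index=phenotypes.index, name="breeding_value"),
        causal_core=causal_core,
        causal_presence=causal_presence,
        causal_vertex_snps=causal_vx,
        var_components=var_components,
        realized_h2=realized_h2,
        sigma2_e=sigma2_e,
    )
    return phenotypes, truth


def simulate_panel(config: SimConfig) -> SimData:
    """Run the three generators with one seed and bundle the pipeline inputs.

    ``calls_by_reference`` groups the vertex SNPs by their source reference
    (plus the core calls under the backbone name), matching how call sets
    arrive from per-reference SNP calling.
    """
    rng = np.random.default_rng(config.seed)
    population = simulate_population(config, rng)
    vertex_sim = simulate_vertices(config, population.subpops, rng)
    phenotypes, truth = simulate_phenotype(population, vertex_sim, config, rng)

    calls_by_reference: dict[str, GenotypeCalls] = {BACKBONE: population.calls}
    for ref in vertex_sim.reference_ranks:
        sids = [s.snp_id for s in vertex_sim.calls.snps if s.source_reference == ref]
        calls_by_reference[ref] = vertex_sim.calls.subset_snps(sids)
    return SimData(
        config=config,
        calls_by_reference=calls_by_reference,
        vertices=vertex_sim.vertices,
        reference_ranks=dict(vertex_sim.reference_ranks),
        phenotypes=phenotypes,
        subpops=population.subpops,
        population=population,
        vertex_sim=vertex_sim,
        truth=truth,
    )
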