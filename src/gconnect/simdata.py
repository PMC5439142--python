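"""Synthetic multi-flock herds with controllable genetic connectedness.

The generator emulates the structure of a national sheep evaluation at desk
scale: several flock contemporary groups, each with its own founder ewes and
rams, a configurable fraction of matings sired by "link" rams shared across
flocks (the mechanism that creates connectedness in real schemes), a single
recorded weight-like trait per animal, and gene-dropped SNP genotypes for a
subset of animals.

Breeding values follow u ~ N(0, sigma_g^2 A) exactly, via the pedigree
recursion u_i = (u_s + u_d)/2 + m_i with Mendelian-sampling variance
sigma_g^2 (0.5 - 0.25 (F_s + F_d)) using exact parental inbreeding — so the
Monte-Carlo covariance target is sigma_g^2 A, not an approximation.  Records
are y = X beta + Z u + e with e ~ N(0, sigma_e^2 I).  Setting
``link_sire_fraction = 0`` yields fully disconnected contemporary groups.

What this emulates and what it does not: real data add selection, non-random
mating, genotype-by-environment structure and missing records; none are
simulated, so passing tests certify the algebra and the estimators, not
robustness to those features.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .genomic import GenotypeMatrix
from .mme import VarianceComponents
from .model_design import Covariate, ModelSpec
from .pedigree import Pedigree, inbreeding, order_pedigree

#: default variance components: sigma_g^2 = 1.81, sigma_e^2 = 7.43
#: (heritability 0.20), the working values for a live-weight trait
DEFAULT_VC = VarianceComponents(sigma_g2=1.81, sigma_e2=7.43)


@dataclass(frozen=True)
class FixedEffectSpec:
    """Other (non-CG) fixed effects to simulate.

    ``factor_levels`` gives the number of levels of each categorical factor
    (e.g. (4,) for a birth-rearing-rank analogue); ``n_covariates`` continuous
    covariates are drawn N(covariate_mean, covariate_sd^2) — the default mean
    of 20 mimics an uncentred weaning-weight covariate, which is what makes
    the correction factor large.  With ``balanced`` the same factor pattern
    and covariate values repeat in every CG, giving exactly equal within-CG
    means.
    """

    factor_levels: tuple[int, ...] = ()
    n_covariates: int = 0
    covariate_mean: float = 20.0
    covariate_sd: float = 4.0
    balanced: bool = False


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic herd."""

    n_cgs: int = 5
    offspring_per_cg: int = 30
    n_generations: int = 2
    sires_per_cg: int = 3
    dams_per_cg: int = 15
    link_sire_fraction: float = 0.3
    n_link_sires: int = 4
    cg_effect_sd: float = 2.0
    vc: VarianceComponents = field(default_factory=lambda: DEFAULT_VC)
    fixed_effects: FixedEffectSpec = field(default_factory=FixedEffectSpec)
    n_markers: int = 0
    genotyped_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.link_sire_fraction <= 1.0:
            raise ValueError("link_sire_fraction must be in [0, 1]")
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ValueError("genotyped_fraction must be in [0, 1]")
        if min(self.n_cgs, self.offspring_per_cg, self.n_generations,
               self.sires_per_cg, self.dams_per_cg) < 1:
            raise ValueError("counts must be >= 1")

    def model_spec(self) -> ModelSpec:
        fe = self.fixed_effects
        return ModelSpec(
            cg="cg",
            factors=tuple(f"factor{k + 1}" for k in range(len(fe.factor_levels))),
            covariates=tuple(Covariate(f"cov{k + 1}") for k in range(fe.n_covariates)),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["vc"] = {"sigma_g2": self.vc.sigma_g2, "sigma_e2": self.vc.sigma_e2}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        if "vc" in d:
            d["vc"] = VarianceComponents(**d["vc"])
        if "fixed_effects" in d:
            fe = dict(d["fixed_effects"])
            fe["factor_levels"] = tuple(fe.get("factor_levels", ()))
            d["fixed_effects"] = FixedEffectSpec(**fe)
        return cls(**d)


def _build_pedigree_triples(sc: SimScenario, rng: np.random.Generator):
    """Mating plan: returns (triples, cg_of_animal, sex_of_animal).

    Founders are private rams/ewes per CG plus a global link-ram pool; each
    offspring's sire is a link ram with probability ``link_sire_fraction``
    (only if connectedness is requested), else a ram of its own CG.
    """
    triples: list[tuple[str, str, str]] = []
    cg_of: dict[str, str] = {}
    males: dict[str, list[str]] = {}
    females: dict[str, list[str]] = {}
    link_pool: list[str] = []

    def add(animal, sire, dam):
        triples.append((animal, sire, dam))

    for c in range(sc.n_cgs):
        cg = f"cg{c + 1:02d}"
        males[cg] = []
        females[cg] = []
        for k in range(sc.sires_per_cg):
            a = f"{cg}_s{k + 1}"
            add(a, "0", "0")
            males[cg].append(a)
        for k in range(sc.dams_per_cg):
            a = f"{cg}_d{k + 1}"
            add(a, "0", "0")
            females[cg].append(a)
    if sc.link_sire_fraction > 0:
        for k in range(sc.n_link_sires):
            a = f"link_s{k + 1}"
            add(a, "0", "0")
            link_pool.append(a)

    for g in range(1, sc.n_generations + 1):
        next_males: dict[str, list[str]] = {}
        next_females: dict[str, list[str]] = {}
        for c in range(sc.n_cgs):
            cg = f"cg{c + 1:02d}"
            next_males[cg] = []
            next_females[cg] = []
            for k in range(sc.offspring_per_cg):
                a = f"{cg}_g{g}_{k + 1}"
                use_link = (sc.link_sire_fraction > 0
                            and rng.random() < sc.link_sire_fraction)
                sire = (link_pool[rng.integers(len(link_pool))] if use_link
                        else males[cg][rng.integers(len(males[cg]))])
                dam = females[cg][rng.integers(len(females[cg]))]
                add(a, sire, dam)
                cg_of[a] = cg
                if rng.random() < 0.5:
                    next_males[cg].append(a)
                else:
                    next_females[cg].append(a)
        for cg in males:
            # carry founders forward if a sex went extinct in a small CG
            males[cg] = next_males[cg] or males[cg]
            females[cg] = next_females[cg] or females[cg]
    return triples, cg_of


def simulate_breeding_values(ped: Pedigree, sigma_g2: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw u ~ N(0, sigma_g^2 A) by the pedigree recursion (no Cholesky).

    Founders get independent N(0, sigma_g^2); descendants get the parental
    mean plus Mendelian sampling with exact inbreeding-adjusted variance.
    """
    n = ped.n
    F = inbreeding(ped)
    u = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        fs = F[s] if s >= 0 else -1.0
        fd = F[d] if d >= 0 else -1.0
        mv = sigma_g2 * (0.5 - 0.25 * (fs + fd))
        mean = 0.0
        if s >= 0:
            mean += 0.5 * u[s]
        if d >= 0:
            mean += 0.5 * u[d]
        u[i] = mean + rng.normal(0.0, np.sqrt(mv))
    return u


def _simulate_fixed_effects(sc: SimScenario, n_rec: int, cg_codes: np.ndarray,
                            rng: np.random.Generator):
    """Non-CG fixed-effect columns and their contribution to the linear predictor."""
    fe = sc.fixed_effects
    cols: dict[str, np.ndarray] = {}
    contrib = np.zeros(n_rec)
    n_cgs = cg_codes.max() + 1
    per_cg = np.bincount(cg_codes, minlength=n_cgs)
    for k, n_lev in enumerate(fe.factor_levels):
        effects = np.concatenate([[0.0], rng.normal(0.0, 1.0, n_lev - 1)])
        if fe.balanced:
            levels = np.empty(n_rec, dtype=int)
            for c in range(n_cgs):
                idx = np.where(cg_codes == c)[0]
                levels[idx] = np.arange(idx.size) % n_lev
        else:
            levels = rng.integers(0, n_lev, n_rec)
        cols[f"factor{k + 1}"] = levels + 1  # 1-based labels
        contrib += effects[levels]
    for k in range(fe.n_covariates):
        slope = rng.normal(0.0, 0.5)
        if fe.balanced:
            base = rng.normal(fe.covariate_mean, fe.covariate_sd, per_cg.max())
            v = np.empty(n_rec)
            for c in range(n_cgs):
                idx = np.where(cg_codes == c)[0]
                v[idx] = base[: idx.size]
        else:
            v = rng.normal(fe.covariate_mean, fe.covariate_sd, n_rec)
        cols[f"cov{k + 1}"] = v
        contrib += slope * v
    return cols, contrib


def simulate_pedigree_and_records(sc: SimScenario) -> tuple[Pedigree, pd.DataFrame]:
    """Simulate the pedigree and the one-record-per-animal phenotype table.

    Records cover every non-founder animal; the returned table has columns
    ``animal, cg, [factor*, cov*], y``.  Identical scenario + seed gives
    identical output.
    """
    rng = np.random.default_rng(sc.seed)
    triples, cg_of = _build_pedigree_triples(sc, rng)
    ped = order_pedigree(triples)
    u = simulate_breeding_values(ped, sc.vc.sigma_g2, rng)

    recorded = [a for a in ped.ids if a in cg_of]
    cg_labels = sorted({cg_of[a] for a in recorded})
    cg_pos = {c: k for k, c in enumerate(cg_labels)}
    cg_codes = np.array([cg_pos[cg_of[a]] for a in recorded])
    n_rec = len(recorded)

    beta_cg = rng.normal(10.0, sc.cg_effect_sd, len(cg_labels))
    cols, contrib = _simulate_fixed_effects(sc, n_rec, cg_codes, rng)
    e = rng.normal(0.0, np.sqrt(sc.vc.sigma_e2), n_rec)
    u_rec = u[ped.indices_of(recorded)]
    y = beta_cg[cg_codes] + contrib + u_rec + e

    data = {"animal": recorded, "cg": [cg_of[a] for a in recorded]}
    data.update(cols)
    data["y"] = y
    return ped, pd.DataFrame(data)


def simulate_genotypes(ped: Pedigree, sc: SimScenario,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Gene-drop SNP genotypes down the pedigree.

    Founder allele frequencies are Uniform(0.1, 0.9) per marker; each
    offspring inherits one uniformly chosen allele per parent (unknown
    parents contribute a fresh population allele).  The genotyped subset is
    the last ``genotyped_fraction`` of animals in pedigree order (youngest
    animals, as in real genotyping campaigns); with fraction 1 or 0 the full
    pedigree or an empty panel is returned.  The returned panel carries the
    true base-population allele frequencies, under which the expectation of
    VanRaden's G is the pedigree A22 block (sample-estimated frequencies on
    a small family panel would re-centre G towards zero).
    """
    if sc.n_markers < 1:
        raise ValueError("n_markers must be >= 1 to simulate genotypes")
    if rng is None:
        rng = np.random.default_rng(sc.seed + 1)
    n, m = ped.n, sc.n_markers
    freqs = rng.uniform(0.1, 0.9, m)
    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        for slot, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                hap[i, slot] = rng.random(m) < freqs
            else:
                pick = rng.integers(0, 2, m)
                hap[i, slot] = hap[parent, pick, np.arange(m)]
    dosages = hap.sum(axis=1).astype(float)

    n_geno = int(round(sc.genotyped_fraction * n))
    idx = np.arange(n - n_geno, n)
    ids = [ped.ids[i] for i in idx]
    return GenotypeMatrix.from_dosages(ids, dosages[idx], allele_freqs=freqs)
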