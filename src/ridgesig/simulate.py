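"""Synthetic genotype/phenotype generator with LD structure.

The generator stands in for a coalescent- or forward-simulated haplotype
panel: a population of H haplotypes over M SNPs is built by a first-order
copying process in which each haplotype's allele at SNP j either copies its
allele at SNP j-1 (with probability ``ld_decay``) or is drawn fresh from a
Bernoulli with that SNP's target allele frequency.  Correlation between
SNPs therefore decays geometrically with distance, and a small fraction of
columns are exact duplicates of their neighbour so that perfect proxies
(r^2 = 1) of a causal SNP occur, as they do in dense real data.

Individuals are formed by drawing two haplotypes with replacement and
summing minor-allele counts, giving Hardy-Weinberg genotypes in {0, 1, 2}.
Phenotypes come in three flavours:

* continuous single-causal: Y_i ~ N(1 + 2k_i, 1), k_i the causal count;
* continuous multi-causal:  Y = X beta + eps, eps ~ N(0, I);
* case-control (liability/penetrance): an individual with k causal minor
  alleles is a case with probability f_k, where under an additive model
  with prevalence K, genotype relative risk r = f1/f0 and causal MAF p,
  f0 = K/(1 - 2p + 2pr), f1 = r f0, f2 = 2 r f0 - f0; sampling repeats
  until n/2 cases and n/2 controls are ascertained.

Null phenotypes are N(0, 1) (continuous) or Binom(1, 0.5) (binary),
independent of genotype.  All randomness flows from a single scenario seed
through ``numpy.random.SeedSequence`` spawning, so every replicate is
independently reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, Phenotype
from .exceptions import ValidationError

#: population size of the default haplotype panel
DEFAULT_PANEL_SIZE = 21_000
#: default copying probability between adjacent SNPs
DEFAULT_LD_DECAY = 0.9
#: default fraction of exact-duplicate (r^2 = 1) columns
DEFAULT_DUP_FRACTION = 0.05
#: default Beta shape for the minor-allele-frequency spectrum on (0.01, 0.5)
DEFAULT_MAF_SHAPE = (1.0, 3.0)


@dataclass
class HaplotypePanel:
    """Population of binary haplotypes over M SNPs (allele 1 = minor).

    ``ld_decay`` records the copying rate for panels built by the Markov
    copying model and is None for coalescent panels, whose LD structure
    comes from the simulated genealogy.
    """

    haplotypes: np.ndarray  # H x M, 0/1
    pop_maf: np.ndarray  # M, in (0, 0.5]
    ld_decay: float | None = None
    seed: int | None = None

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class DiseaseModel:
    """Additive penetrance model for case-control ascertainment.

    K is the population prevalence and r = f1/f0 the genotype relative
    risk.  Penetrances are resolved against the causal SNP's population
    minor-allele frequency p via :meth:`penetrances`.
    """

    K: float = 0.10
    r: float = 2.0

    def __post_init__(self):
        if not 0 < self.K < 1:
            raise ValidationError("prevalence K must lie in (0, 1)")
        if self.r <= 0:
            raise ValidationError("genotype relative risk r must be > 0")

    def penetrances(self, p: float) -> tuple[float, float, float]:
        """(f0, f1, f2) for causal minor-allele frequency p."""
        if not 0 < p <= 0.5:
            raise ValidationError("causal MAF p must lie in (0, 0.5]")
        f0 = self.K / (1.0 - 2.0 * p + 2.0 * p * self.r)
        f1 = self.r * f0
        f2 = 2.0 * self.r * f0 - f0
        for name, f in (("f0", f0), ("f1", f1), ("f2", f2)):
            if not 0.0 < f <= 1.0:
                raise ValidationError(
                    f"penetrance {name} = {f:.4g} outside (0, 1] for "
                    f"K={self.K}, r={self.r}, p={p}; reduce K or r"
                )
        return f0, f1, f2


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario (one table cell family)."""

    n: int = 500
    m: int = 20
    phenotype_kind: str = "continuous"  # "continuous" | "binary"
    effect_model: str = "single"  # "null" | "single" | "multi"
    n_causal: int = 1
    effect_size: float = 1.0
    maf_range: tuple[float, float] = (0.10, 0.15)
    lam_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    replicates: int = 10
    alpha: float = 0.05
    seed: int | None = None
    disease: DiseaseModel = field(default_factory=DiseaseModel)

    def __post_init__(self):
        if self.n < 1 or self.m < 1:
            raise ValidationError("n and m must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5):
            raise ValidationError("maf_range must be an interval inside (0, 0.5)")
        if self.phenotype_kind not in ("continuous", "binary"):
            raise ValidationError(f"unknown phenotype kind {self.phenotype_kind!r}")
        if self.effect_model not in ("null", "single", "multi"):
            raise ValidationError(f"unknown effect model {self.effect_model!r}")


# ----------------------------------------------------------------------
def build_haplotype_panel(H: int = DEFAULT_PANEL_SIZE, M: int = 1000,
                          ld_decay: float = DEFAULT_LD_DECAY,
                          maf_shape: tuple[float, float] = DEFAULT_MAF_SHAPE,
                          seed: int | None = None,
                          dup_fraction: float = DEFAULT_DUP_FRACTION) -> HaplotypePanel:
    """Build an LD-structured haplotype panel by first-order copying.

    Parameters
    ----------
    H, M : int
        Number of haplotypes and SNPs.
    ld_decay : float in [0, 1]
        Probability that a haplotype copies its previous-SNP allele; 0
        gives independent SNPs, 1 gives a single repeated column.
    maf_shape : (a, b)
        Beta(a, b) shape of the allele-frequency spectrum, mapped onto
        (0.01, 0.5).
    dup_fraction : float in [0, 1)
        Fraction of columns that exactly duplicate their left neighbour.
    """
    if H < 2 or M < 1:
        raise ValidationError("panel needs H >= 2 haplotypes and M >= 1 SNPs")
    if not 0 <= ld_decay <= 1:
        raise ValidationError("ld_decay must lie in [0, 1]")
    if not 0 <= dup_fraction < 1:
        raise ValidationError("dup_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    a, b = maf_shape
    target = 0.01 + 0.49 * rng.beta(a, b, size=M)
    hap = np.empty((H, M), dtype=np.int8)
    hap[:, 0] = rng.random(H) < target[0]
    for j in range(1, M):
        if dup_fraction > 0 and rng.random() < dup_fraction:
            hap[:, j] = hap[:, j - 1]
            continue
        fresh = rng.random(H) < target[j]
        if ld_decay >= 1.0:
            hap[:, j] = hap[:, j - 1]
        elif ld_decay <= 0.0:
            hap[:, j] = fresh
        else:
            copy = rng.random(H) < ld_decay
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    freq = hap.mean(axis=0)
    # re-draw monomorphic columns (vanishingly rare for H >> 1/maf) and
    # flip coding so allele 1 is always the minor allele
    for j in np.where((freq == 0) | (freq == 1))[0]:
        hap[:, j] = rng.random(H) < max(target[j], 0.05)
        freq[j] = hap[:, j].mean()
    flip = freq > 0.5
    hap[:, flip] = 1 - hap[:, flip]
    pop_maf = np.minimum(freq, 1.0 - freq)
    return HaplotypePanel(haplotypes=hap, pop_maf=pop_maf, ld_decay=ld_decay, seed=seed)


def build_coalescent_panel(n_haplotypes: int = DEFAULT_PANEL_SIZE,
                           sequence_length: float = 1e6,
                           recombination_rate: float = 1e-8,
                           mutation_rate: float = 2.5e-8,
                           population_size: float = 10_500,
                           seed: int | None = None) -> HaplotypePanel:
    """Simulate a neutral coalescent haplotype panel (the default study panel).

    Emulates a large forward-simulated population sample: 21,000 haplotypes
    over a 1 Mb region with human-like recombination (1e-8 /bp/gen) and a
    mutation rate chosen so the region carries roughly 10,000 segregating
    sites, giving a realistic site-frequency spectrum (most SNPs rare) and
    block-like LD in which correlation with any focal SNP ranges from ~0 to
    perfect (r^2 = 1).  Alleles are recoded so 1 is the minor allele.
    """
    import msprime

    if n_haplotypes < 2 or n_haplotypes % 2:
        raise ValidationError("n_haplotypes must be even (diploid samples) and >= 2")
    rng = np.random.default_rng(seed)
    s1, s2 = (int(v) for v in rng.integers(1, 2**31, size=2))
    anc = msprime.sim_ancestry(
        samples=n_haplotypes // 2, ploidy=2, population_size=population_size,
        sequence_length=sequence_length, recombination_rate=recombination_rate,
        random_seed=s1,
    )
    ts = msprime.sim_mutations(anc, rate=mutation_rate, random_seed=s2,
                               model=msprime.BinaryMutationModel())
    hap = np.empty((ts.num_samples, ts.num_sites), dtype=np.int8)
    for j, var in enumerate(ts.variants()):
        hap[:, j] = var.genotypes
    freq = hap.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    hap, freq = hap[:, keep], freq[keep]
    flip = freq > 0.5
    hap[:, flip] = 1 - hap[:, flip]
    return HaplotypePanel(haplotypes=hap, pop_maf=np.minimum(freq, 1.0 - freq),
                          ld_decay=None, seed=seed)


def designate_causal(panel: HaplotypePanel, maf_range=(0.10, 0.15),
                     n_causal: int = 1, seed=None,
                     candidate_indices=None) -> np.ndarray:
    """Uniformly choose causal SNP indices among those with MAF in range."""
    rng = np.random.default_rng(seed)
    lo, hi = maf_range
    pool = (np.asarray(candidate_indices, dtype=int)
            if candidate_indices is not None else np.arange(panel.n_snps))
    eligible = pool[(panel.pop_maf[pool] >= lo) & (panel.pop_maf[pool] <= hi)]
    if eligible.size < n_causal:
        raise ValidationError(
            f"only {eligible.size} SNPs with MAF in [{lo}, {hi}] "
            f"(need {n_causal}); widen the range or enlarge the panel"
        )
    return np.sort(rng.choice(eligible, size=n_causal, replace=False))


def choose_window(panel: HaplotypePanel, m: int, causal_index: int | None = None,
                  seed=None) -> np.ndarray:
    """Random contiguous window of m SNPs, containing the causal SNP if given."""
    if m > panel.n_snps:
        raise ValidationError(f"window m={m} exceeds panel size {panel.n_snps}")
    rng = np.random.default_rng(seed)
    if causal_index is None:
        start = rng.integers(0, panel.n_snps - m + 1)
    else:
        lo = max(0, causal_index - m + 1)
        hi = min(panel.n_snps - m, causal_index)
        start = rng.integers(lo, hi + 1)
    return np.arange(start, start + m)


def sample_genotypes(panel: HaplotypePanel, n: int, seed=None,
                     snp_indices=None) -> GenotypeMatrix:
    """Draw n genotypes as sums of two haplotypes sampled with replacement."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = (np.asarray(snp_indices, dtype=int) if snp_indices is not None
            else np.arange(panel.n_snps))
    idx = rng.integers(0, panel.n_haplotypes, size=(2, n))
    sub = panel.haplotypes[:, cols]
    geno = sub[idx[0]].astype(np.int16) + sub[idx[1]]
    ids = np.array([f"snp{j}" for j in cols], dtype=object)
    return GenotypeMatrix(values=geno.astype(float), snp_ids=ids)


def simulate_continuous_phenotype(G: GenotypeMatrix, causal_idx, config=None,
                                  seed=None, mode: str = "single",
                                  effect_size: float = 1.0) -> Phenotype:
    """Continuous phenotype under the null, single- or multi-causal model.

    ``causal_idx`` indexes columns of G (raw allele counts).  Modes:
    ``"null"`` Y_i ~ N(0,1); ``"single"`` Y_i ~ N(1 + 2k_i, 1);
    ``"multi"`` Y = X beta + eps with beta = effect_size at causal columns.
    """
    if config is not None:
        mode = config.effect_model
        effect_size = config.effect_size
    rng = np.random.default_rng(seed)
    n = G.n_samples
    causal = np.atleast_1d(np.asarray(causal_idx, dtype=int)) if causal_idx is not None else np.array([], dtype=int)
    if mode == "null":
        if causal.size:
            raise ValidationError("null mode admits no causal SNPs")
        y = rng.standard_normal(n)
    elif mode == "single":
        if causal.size != 1:
            raise ValidationError("single-causal mode needs exactly one causal index")
        k = G.values[:, causal[0]]
        y = rng.normal(loc=1.0 + 2.0 * k, scale=1.0)
    elif mode == "multi":
        if causal.size < 1:
            raise ValidationError("multi-causal mode needs at least one causal index")
        beta = np.zeros(G.n_snps)
        beta[causal] = effect_size
        y = G.values @ beta + rng.standard_normal(n)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return Phenotype(y=y, kind="continuous")


def simulate_binary_phenotype(panel: HaplotypePanel, causal_index: int,
                              disease: DiseaseModel, n: int, seed=None,
                              snp_indices=None,
                              ) -> tuple[GenotypeMatrix, Phenotype]:
    """Ascertain n/2 cases and n/2 controls under the penetrance model.

    Individuals are generated one cohort batch at a time; each is a case
    with probability f_k given its causal minor-allele count k, and kept
    only while its class still needs members.
    """
    if n < 2 or n % 2:
        raise ValidationError("n must be even and >= 2 (n/2 cases, n/2 controls)")
    rng = np.random.default_rng(seed)
    cols = (np.asarray(snp_indices, dtype=int) if snp_indices is not None
            else np.arange(panel.n_snps))
    if causal_index not in cols:
        raise ValidationError("causal SNP must lie inside the sampled window")
    causal_pos = int(np.where(cols == causal_index)[0][0])
    p = float(panel.pop_maf[causal_index])
    f = np.array(disease.penetrances(p))
    sub = panel.haplotypes[:, cols]
    half = n // 2
    cases, controls = [], []
    while len(cases) < half or len(controls) < half:
        batch = max(256, n)
        idx = rng.integers(0, panel.n_haplotypes, size=(2, batch))
        geno = sub[idx[0]].astype(np.int16) + sub[idx[1]]
        k = geno[:, causal_pos]
        is_case = rng.random(batch) < f[k]
        for g, c in zip(geno, is_case):
            if c and len(cases) < half:
                cases.append(g)
            elif not c and len(controls) < half:
                controls.append(g)
            if len(cases) >= half and len(controls) >= half:
                break
    geno = np.vstack(cases + controls).astype(float)
    y = np.concatenate([np.ones(half), np.zeros(half)])
    # shuffle rows so case/control order carries no information
    order = rng.permutation(n)
    ids = np.array([f"snp{j}" for j in cols], dtype=object)
    G = GenotypeMatrix(values=geno[order], snp_ids=ids)
    return G, Phenotype(y=y[order], kind="binary")


def simulate_null_binary_phenotype(n: int, seed=None) -> Phenotype:
    """Null binary phenotype Y_i ~ Binom(1, 0.5), independent of genotype."""
    rng = np.random.default_rng(seed)
    return Phenotype(y=rng.integers(0, 2, size=n).astype(float), kind="binary")


# ----------------------------------------------------------------------
def simulate_replicate(panel: HaplotypePanel, config: ScenarioConfig,
                       seed_seq: np.random.SeedSequence,
                       ) -> tuple[GenotypeMatrix, Phenotype, np.ndarray]:
    """Generate one replicate (raw genotypes, phenotype, causal window positions).

    The returned causal positions index columns of the raw genotype matrix;
    map them through ``preprocess(...).source_index`` after preprocessing.
    """
    seeds = seed_seq.spawn(4)
    if config.effect_model == "null":
        window = choose_window(panel, config.m, seed=seeds[0])
        G = sample_genotypes(panel, config.n, seed=seeds[1], snp_indices=window)
        if config.phenotype_kind == "continuous":
            y = simulate_continuous_phenotype(G, None, seed=seeds[2], mode="null")
        else:
            y = simulate_null_binary_phenotype(config.n, seed=seeds[2])
        return G, y, np.array([], dtype=int)

    if config.effect_model == "single":
        causal = int(designate_causal(panel, config.maf_range, 1, seed=seeds[0])[0])
        window = choose_window(panel, config.m, causal_index=causal, seed=seeds[1])
        causal_pos = np.array([causal - window[0]], dtype=int)
        if config.phenotype_kind == "continuous":
            G = sample_genotypes(panel, config.n, seed=seeds[2], snp_indices=window)
            y = simulate_continuous_phenotype(G, causal_pos, seed=seeds[3], mode="single")
        else:
            G, y = simulate_binary_phenotype(panel, causal, config.disease,
                                             config.n, seed=seeds[2],
                                             snp_indices=window)
        return G, y, causal_pos

    # multi-causal: pick a window holding enough eligible SNPs (uniformly
    # among all qualifying windows), then designate the causal set inside it
    if config.phenotype_kind != "continuous":
        raise ValidationError("multi-causal scenarios are continuous-phenotype only")
    lo, hi = config.maf_range
    eligible = ((panel.pop_maf >= lo) & (panel.pop_maf <= hi)).astype(int)
    window_counts = np.convolve(eligible, np.ones(config.m, dtype=int), "valid")
    starts = np.where(window_counts >= config.n_causal)[0]
    if starts.size == 0:
        raise ValidationError(
            f"no window of {config.m} SNPs holds {config.n_causal} SNPs "
            f"with MAF in {config.maf_range}; widen the range or the window"
        )
    start = int(np.random.default_rng(seeds[0]).choice(starts))
    window = np.arange(start, start + config.m)
    causal = designate_causal(panel, config.maf_range, config.n_causal,
                              seed=seeds[1], candidate_indices=window)
    causal_pos = causal - window[0]
    G = sample_genotypes(panel, config.n, seed=seeds[2], snp_indices=window)
    y = simulate_continuous_phenotype(G, causal_pos, seed=seeds[3], mode="multi",
                                      effect_size=config.effect_size)
    return G, y, causal_pos
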