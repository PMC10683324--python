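"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The real mapping population (intensively selected beef cows phenotyped for
~11 correlated conformation traits) is under a restricted license, so every
downstream stage is exercised on cohorts built here: LD-block-structured
diploid genotypes from a founder-haplotype mosaic, correlated trait
deviations with a shared marker-based polygenic background, pleiotropic
large-effect QTL whose size-trait and muscling-trait effects are negatively
correlated, recessive deleterious variants with favorable additive effects,
and VEP-like coding annotations at a genome-wide rate of 0.34%.

Genotypes are hard calls in {0, 1, 2}; fractional dosages (as produced by
imputation) are obtained by :func:`add_dosage_noise`. The polygenic term is
realized as a scaled sum over the simulated background markers, so a GRM
built from those same markers is internally consistent and heritability
recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationTable, GenotypeMatrix, PhenotypeTable


def _check_psd(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise ValueError(f"{name} must be positive semi-definite")
    return mat


@dataclass
class QtlSpec:
    """A single simulated causal variant.

    ``effects`` is the additive effect per alternate-allele dose on each
    trait; ``recessive_penalty`` (if set) is added to the phenotype of
    homozygous-alternate carriers on every trait, modelling recessive
    deleterious alleles kept frequent by favorable additive effects
    (heterozygote advantage).
    """

    chrom: str
    position: int
    effects: np.ndarray
    frequency_target: float = 0.25
    recessive_penalty: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if not 0.0 < self.frequency_target < 1.0:
            raise ValueError("frequency_target must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    ``block_length_bp`` is the expected physical length of a founder-copying
    block; together with ``switch_rate`` (per-variant probability of
    switching to a random founder) it sets the inter-variant spacing to
    ``block_length_bp * switch_rate`` so that LD decays on the intended
    physical scale.
    """

    n_individuals: int = 1000
    n_chromosomes: int = 2
    n_variants_per_chrom: int = 500
    n_founder_haplotypes: int = 100
    block_length_bp: int = 250_000
    switch_rate: float = 0.05
    proxy_rate: float = 0.15
    maf_floor: float = 0.02
    traits: list[str] = field(default_factory=lambda: ["trait1", "trait2"])
    Vg: np.ndarray | None = None
    Ve: np.ndarray | None = None
    qtl_spec: list[QtlSpec] = field(default_factory=list)
    coding_rate: float = 0.0034
    background_chroms: list[str] | None = None  # None: all chromosomes
    seed: int = 0

    def __post_init__(self) -> None:
        t = len(self.traits)
        if self.Vg is None:
            self.Vg = np.eye(t) * 0.3
        if self.Ve is None:
            self.Ve = np.eye(t) * 0.7
        self.Vg = _check_psd(self.Vg, "Vg")
        self.Ve = _check_psd(self.Ve, "Ve")
        if self.Vg.shape[0] != t or self.Ve.shape[0] != t:
            raise ValueError("Vg/Ve dimension must equal the number of traits")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        if not 0.0 <= self.coding_rate <= 1.0:
            raise ValueError("coding_rate must be in [0, 1]")
        if not 0.0 <= self.switch_rate <= 1.0:
            raise ValueError("switch_rate must be in [0, 1]")
        if not 0.0 <= self.proxy_rate <= 1.0:
            raise ValueError("proxy_rate must be in [0, 1]")
        if self.n_founder_haplotypes < 2:
            raise ValueError("need at least two founder haplotypes")
        for q in self.qtl_spec:
            if len(q.effects) != t:
                raise ValueError("QTL effects length must equal number of traits")
            if not self._chrom_valid(q.chrom):
                raise ValueError(f"QTL chromosome {q.chrom} not simulated")
            if not 1 <= q.position <= self.chrom_length_bp():
                raise ValueError(
                    f"QTL position {q.position} outside simulated range "
                    f"[1, {self.chrom_length_bp()}]"
                )

    def _chrom_valid(self, chrom: str) -> bool:
        return chrom in self.chrom_names()

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def spacing_bp(self) -> int:
        return max(1, int(round(self.block_length_bp * max(self.switch_rate, 1e-3))))

    def chrom_length_bp(self) -> int:
        return self.spacing_bp() * self.n_variants_per_chrom


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated cohort."""

    causal_ids: list[str]
    effects: dict[str, np.ndarray]  # variant id -> per-trait additive effect
    recessive_penalties: dict[str, float]
    g: np.ndarray  # (n, T) polygenic values
    e: np.ndarray  # (n, T) residuals
    qtl_component: np.ndarray  # (n, T) summed QTL contribution
    realized_Vg: np.ndarray
    realized_Ve: np.ndarray


def _mosaic_haplotypes(
    rng: np.random.Generator,
    n_haplotypes: int,
    n_variants: int,
    n_founders: int,
    switch_rate: float,
) -> np.ndarray:
    """Founder index path for each haplotype (copying with random switches)."""
    paths = np.empty((n_haplotypes, n_variants), dtype=np.int32)
    current = rng.integers(0, n_founders, size=n_haplotypes)
    paths[:, 0] = current
    if n_variants > 1:
        switch = rng.random((n_haplotypes, n_variants - 1)) < switch_rate
        new_src = rng.integers(0, n_founders, size=(n_haplotypes, n_variants - 1))
        for j in range(1, n_variants):
            current = np.where(switch[:, j - 1], new_src[:, j - 1], current)
            paths[:, j] = current
    return paths


def _founder_alleles(
    rng: np.random.Generator,
    n_founders: int,
    freqs: np.ndarray,
    phi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Founder allele matrix with AR(1)-correlated columns.

    A latent Gaussian per founder evolves along the chromosome with
    per-step autocorrelation ``phi``; alleles are set by rank-thresholding
    each column at its target frequency, so founder allele counts match the
    frequency spectrum while neighboring columns stay strongly correlated
    (this is what creates high-r2 LD blocks).
    """
    m = freqs.shape[0]
    z = np.empty((n_founders, m))
    z[:, 0] = rng.standard_normal(n_founders)
    if m > 1:
        eps = rng.standard_normal((n_founders, m - 1))
        scale = np.sqrt(max(1.0 - phi**2, 0.0))
        for j in range(1, m):
            z[:, j] = phi * z[:, j - 1] + scale * eps[:, j - 1]
    k = np.clip(np.round(n_founders * freqs).astype(int), 1, n_founders - 1)
    ranks = np.argsort(np.argsort(z, axis=0), axis=0)  # 0 = smallest latent
    alleles = (ranks < k[None, :]).astype(np.int8)
    return alleles, z


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Simulate hard-call dosages with block LD from a founder mosaic.

    Each individual carries two haplotypes; each haplotype copies a founder
    haplotype and switches to a random founder with probability
    ``switch_rate`` per variant. Founder allele columns are themselves
    correlated along the chromosome (latent AR(1) with step correlation
    ``exp(-switch_rate)``), so nearby variants sit in high-r2 blocks and r2
    decays with physical distance both through founder switching and
    through founder-level decorrelation. Target frequencies come from a
    U(0.05, 0.95) spectrum; variants whose realized MAF falls below
    ``maf_floor`` are re-thresholded at a safer frequency a few times and
    dropped if still failing. At every QTL position a variant is forced to
    exist with frequency near the QTL's target.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    m = config.n_variants_per_chrom
    nf = config.n_founder_haplotypes
    spacing = config.spacing_bp()
    phi = float(np.exp(-config.switch_rate))

    all_dos: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    for chrom in config.chrom_names():
        positions = spacing * np.arange(1, m + 1)
        # snap a variant onto each QTL position on this chromosome
        qtl_here = [q for q in config.qtl_spec if q.chrom == chrom]
        qtl_col: dict[int, QtlSpec] = {}
        for q in qtl_here:
            j = int(np.argmin(np.abs(positions - q.position)))
            while j in qtl_col:  # two QTL snapping to the same column
                j += 1
            positions[j] = q.position
            qtl_col[j] = q
        order = np.argsort(positions)
        positions = positions[order]
        qtl_col = {int(np.flatnonzero(order == j)[0]): q for j, q in qtl_col.items()}
        if np.any(np.diff(positions) <= 0):
            raise ValueError("QTL positions collide with the variant grid")

        # frequency spectrum U(0.05, 0.95), locally correlated along the
        # chromosome (neighboring variants share similar frequencies, a
        # prerequisite for the near-perfect-proxy pairs real sequence data has)
        u = np.empty(m)
        u[0] = rng.standard_normal()
        if m > 1:
            eps_f = rng.standard_normal(m - 1)
            scale = np.sqrt(max(1.0 - phi**2, 0.0))
            for j in range(1, m):
                u[j] = phi * u[j - 1] + scale * eps_f[j - 1]
        freqs = 0.05 + 0.90 * stats.norm.cdf(u)
        for j, q in qtl_col.items():
            freqs[j] = q.frequency_target
        founders, z = _founder_alleles(rng, nf, freqs, phi)
        # proxy variants: copy the previous founder column (sometimes with a
        # single founder flipped), yielding population r2 at or just below 1
        dup = rng.random(m) < config.proxy_rate
        dup[0] = False
        for j in qtl_col:  # QTL columns keep their own target frequency
            dup[j] = False
        flip = rng.random(m) < 0.5
        flip_who = rng.integers(0, nf, size=m)
        for j in range(1, m):
            if dup[j]:
                founders[:, j] = founders[:, j - 1]
                freqs[j] = freqs[j - 1]
                if flip[j]:
                    founders[flip_who[j], j] = 1 - founders[flip_who[j], j]
        paths = _mosaic_haplotypes(rng, 2 * n, m, nf, config.switch_rate)
        hap = founders[paths, np.arange(m)]  # (2n, m)
        dos = (hap[0::2] + hap[1::2]).astype(float)

        # re-threshold columns failing the MAF floor (same latent, safer freq)
        ranks = np.argsort(np.argsort(z, axis=0), axis=0)
        for _ in range(5):
            p = dos.mean(axis=0) / 2.0
            low = np.minimum(p, 1 - p) < config.maf_floor
            low[list(qtl_col)] = False  # QTL columns keep their target frequency
            if not low.any():
                break
            cols = np.flatnonzero(low)
            freqs[cols] = rng.uniform(0.25, 0.75, size=cols.size)
            k = np.clip(np.round(nf * freqs[cols]).astype(int), 1, nf - 1)
            founders[:, cols] = (ranks[:, cols] < k[None, :]).astype(np.int8)
            hap_new = founders[paths[:, cols], cols]
            dos[:, cols] = hap_new[0::2] + hap_new[1::2]

        p = dos.mean(axis=0) / 2.0
        keep = np.minimum(p, 1 - p) >= config.maf_floor
        for j in qtl_col:
            keep[j] = True
        names = [
            f"{chrom}:{pos}" if j not in qtl_col or qtl_col[j].name is None
            else qtl_col[j].name
            for j, pos in enumerate(positions)
        ]
        frame = pd.DataFrame(
            {
                "variant_id": names,
                "chrom": chrom,
                "pos": positions,
                "ref": "A",
                "alt": "C",
                "alt_freq": p,
                "accuracy": np.nan,
            }
        )
        all_dos.append(dos[:, keep])
        frames.append(frame[keep].reset_index(drop=True))

    variants = pd.concat(frames, ignore_index=True)
    dosages = np.concatenate(all_dos, axis=1)
    ids = [f"id{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages=dosages, variants=variants, individual_ids=ids)


def add_dosage_noise(
    geno: GenotypeMatrix, sd: float = 0.1, seed: int = 0
) -> GenotypeMatrix:
    """Fractional dosages: hard calls plus bounded noise, clipped to [0, 2]."""
    rng = np.random.default_rng(seed)
    noisy = np.clip(
        geno.dosages + rng.normal(0.0, sd, size=geno.dosages.shape), 0.0, 2.0
    )
    return GenotypeMatrix(
        dosages=noisy, variants=geno.variants.copy(),
        individual_ids=list(geno.individual_ids),
    )


def _qtl_variant_index(geno: GenotypeMatrix, q: QtlSpec) -> int:
    hit = (geno.variants["chrom"] == q.chrom) & (geno.variants["pos"] == q.position)
    idx = np.flatnonzero(hit.to_numpy())
    if idx.size == 0:
        raise ValueError(
            f"QTL position {q.chrom}:{q.position} absent from the genotype matrix"
        )
    return int(idx[0])


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimulationConfig
) -> tuple[PhenotypeTable, SimulationTruth]:
    """Simulate trait deviations Y = QTL effects + polygenic + residual.

    The polygenic term g is a centered-marker score over all non-QTL
    variants, scaled so its per-individual covariance matches ``Vg``; since
    the association model builds its GRM from these same markers, estimated
    heritability is comparable to the simulated one. Residuals are i.i.d.
    multivariate normal with covariance ``Ve``. QTL contribute additively
    per allele dose, plus ``recessive_penalty`` for dosage-2 carriers.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = geno.n_individuals
    t = len(config.traits)

    qtl_idx = [(q, _qtl_variant_index(geno, q)) for q in config.qtl_spec]
    background = np.setdiff1d(
        np.arange(geno.n_variants), [j for _, j in qtl_idx]
    )
    if config.background_chroms is not None:
        in_bg = geno.variants["chrom"].isin(config.background_chroms).to_numpy()
        background = background[in_bg[background]]

    # polygenic values: centered marker score scaled to Vg
    g = np.zeros((n, t))
    if background.size and np.any(np.diag(config.Vg) > 0):
        W = geno.dosages[:, background]
        p = W.mean(axis=0) / 2.0
        W = W - 2.0 * p
        denom = 2.0 * np.sum(p * (1 - p))
        L = np.linalg.cholesky(config.Vg + 1e-12 * np.eye(t))
        U = rng.standard_normal((background.size, t)) @ L.T / np.sqrt(denom)
        g = W @ U

    e = rng.multivariate_normal(np.zeros(t), config.Ve, size=n)

    qtl_component = np.zeros((n, t))
    effects: dict[str, np.ndarray] = {}
    penalties: dict[str, float] = {}
    causal_ids: list[str] = []
    for q, j in qtl_idx:
        x = geno.dosages[:, j]
        vid = str(geno.variants.loc[j, "variant_id"])
        causal_ids.append(vid)
        effects[vid] = q.effects.copy()
        qtl_component += np.outer(x, q.effects)
        if q.recessive_penalty is not None:
            penalties[vid] = float(q.recessive_penalty)
            qtl_component[x >= 1.5] += q.recessive_penalty

    Y = qtl_component + g + e
    pheno = PhenotypeTable(
        individual_ids=list(geno.individual_ids),
        trait_names=list(config.traits),
        values=Y,
    )
    truth = SimulationTruth(
        causal_ids=causal_ids,
        effects=effects,
        recessive_penalties=penalties,
        g=g,
        e=e,
        qtl_component=qtl_component,
        realized_Vg=np.cov(g, rowvar=False).reshape(t, t),
        realized_Ve=np.cov(e, rowvar=False).reshape(t, t),
    )
    return pheno, truth


def simulate_annotations(
    geno: GenotypeMatrix,
    coding_rate: float = 0.0034,
    seed: int = 0,
    force_coding: list[str] | None = None,
) -> AnnotationTable:
    """Flag variants coding (MODERATE/HIGH impact) i.i.d. at ``coding_rate``.

    ``force_coding`` lets truth variants be made coding regardless of the
    draw, mimicking the causal missense/frameshift candidates.
    """
    if not 0.0 <= coding_rate <= 1.0:
        raise ValueError("coding_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = geno.n_variants
    coding = rng.random(m) < coding_rate
    if force_coding:
        forced = np.isin(geno.variant_ids, list(force_coding))
        coding = coding | forced

    # gene labels in 1-Mb-scale blocks, purely decorative but position-coherent
    gene = [
        f"GENE_{c}_{int(p) // 1_000_000}"
        for c, p in zip(geno.variants["chrom"], geno.variants["pos"])
    ]
    high = rng.random(m) < 0.15  # minority of coding variants are LoF-like
    impact = np.where(coding, np.where(high, "HIGH", "MODERATE"), "MODIFIER")
    low_mask = (~coding) & (rng.random(m) < 0.02)
    impact = np.where(low_mask, "LOW", impact)
    consequence = np.select(
        [impact == "HIGH", impact == "MODERATE", impact == "LOW"],
        ["frameshift_variant", "missense_variant", "synonymous_variant"],
        default="intergenic_variant",
    )
    sift = np.where(impact == "MODERATE", np.round(rng.uniform(0, 0.2, m), 3), np.nan)
    table = pd.DataFrame(
        {
            "variant_id": geno.variant_ids,
            "consequence": consequence,
            "impact": impact,
            "gene": gene,
            "sift": sift,
        }
    )
    return AnnotationTable(table=table)


def default_cohort_config(
    n_individuals: int = 1500,
    seed: int = 7,
    n_chromosomes: int = 3,
    n_variants_per_chrom: int = 700,
) -> SimulationConfig:
    """Study-like defaults: 11 correlated conformation traits in two blocks.

    Six size traits (height, length, pelvis length/width, chest width, rib
    shape) and five muscling traits share a polygenic background with
    moderate heritability (h2 = 0.3), positive genetic correlation 0.5
    within a block and -0.3 across blocks. Three pleiotropic QTL have
    opposite-sign effects on the two blocks; one is a recessive deleterious
    variant with favorable additive effects kept at low frequency.
    """
    traits = [
        "height", "length", "pelvis_length", "pelvis_width", "chest_width",
        "rib_shape", "top_muscling", "shoulder_muscling", "buttock_side",
        "buttock_rear", "rump",
    ]
    t = len(traits)
    size_block = np.arange(6)

    def block_cov(total, within, across):
        mat = np.full((t, t), across * total)
        for blk in (size_block, np.arange(6, t)):
            mat[np.ix_(blk, blk)] = within * total
        np.fill_diagonal(mat, total)
        eigval, eigvec = np.linalg.eigh(mat)  # nearest-PSD projection
        return eigvec @ np.diag(np.clip(eigval, 1e-6, None)) @ eigvec.T

    Vg = block_cov(0.3, within=0.5, across=-0.3)
    Ve = block_cov(0.7, within=0.35, across=0.0)

    cfg = SimulationConfig(
        n_individuals=n_individuals,
        n_chromosomes=n_chromosomes,
        n_variants_per_chrom=n_variants_per_chrom,
        n_founder_haplotypes=120,
        block_length_bp=250_000,
        switch_rate=0.08,
        maf_floor=0.02,
        traits=traits,
        Vg=Vg,
        Ve=Ve,
        seed=seed,
    )
    span = cfg.chrom_length_bp()
    up = np.array([0.25] * 6 + [-0.15] * 5)  # taller but less muscled
    down = np.array([-0.15] * 6 + [0.25] * 5)
    favorable = np.array([0.12] * 6 + [0.28] * 5)
    cfg.qtl_spec = [
        QtlSpec("chr1", int(span * 0.30), up,
                frequency_target=0.30, name="qtl_size"),
        QtlSpec("chr2", int(span * 0.55), down,
                frequency_target=0.45, name="qtl_muscle"),
        QtlSpec("chr3", int(span * 0.70), favorable,
                frequency_target=0.15, recessive_penalty=-1.5,
                name="qtl_recessive"),
    ]
    cfg.__post_init__()  # re-validate after attaching QTL
    return cfg
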