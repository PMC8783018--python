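"""Synthetic transcriptome generator with feature-driven confounding.

Emulates a bulk developmental-brain expression panel: a genes x samples
matrix of RPKM-like values over a regions x stages x sexes sample grid,
plus the per-gene feature table (abundance, gDNA size, GC content).

The generative model is a log-normal latent-factor model.  For gene g and
sample s,

    z_gs = sum_k l_gk F_ks  +  m_g * H_s  +  sigma * eps_gs,
    Y_gs = a_g * exp(z_gs) / mean_s exp(z_gs),

where F are shared latent factors whose gene loadings l_gk are smooth
functions of the gene's feature quantiles scaled by the confound
strengths, H is a private factor shared only by a planted module's
members, and a_g is the gene's drawn abundance.  Row-rescaling by the
realized mean of exp(z) makes the feature-table abundance equal the
realized row mean exactly while leaving Pearson correlations untouched.

Because loadings vary smoothly with features, genes with similar feature
ranks are correlated through the shared factors alone — the confounding
that matched-set permutation is designed to absorb.  Planted modules add
correlation beyond what features explain; decoy "twin" genes copy the
module's feature profile (jittered) without the private factor, so a
feature-matched but functionally empty set exists by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import ExpressionMatrix, GeneFeatureTable, GeneSet, MgcaDataError

__all__ = [
    "ModuleSpec",
    "SyntheticSpec",
    "SyntheticData",
    "generate",
    "make_confounded_decoy",
]


@dataclass
class ModuleSpec:
    """A planted co-expression module.

    size: number of member genes.
    target_cc: desired mean pairwise Pearson correlation among members on
        the raw expression scale; the private-factor loading is calibrated
        against the model's closed-form log-normal correlation, so the
        realized mean sits near the target.
    abundance_q, size_q, gc_q: quantile windows of the genome-wide feature
        marginals from which member features are drawn.  The default
        biases abundance only (upper ~45% of expression) and leaves size
        and GC genome-typical, so the module's feature-driven
        co-expression advantage flows through a single axis that the
        corresponding matched condition can absorb.  The abundance window
        reaches the top of the range because the seed-abundance filter
        truncates the analysed universe at the module's own minimum:
        module and retained-genome abundance profiles then coincide.
    regions: if given, the module's private factor is active only in
        samples from these regions (for stratified-rerun tests).
    with_decoy: also plant one feature-twin decoy gene per member.
    decoy_noise_frac: residual-noise multiplier for decoy genes.  Decoys
        emulate a worst-case confounded gene set — high mutual
        co-expression driven purely by the shared feature-tied factors —
        which requires feature-driven loading to dominate residual noise;
        the default keeps a quarter of the genome-wide noise sd.
    """

    size: int = 101
    target_cc: float = 0.5
    abundance_q: tuple[float, float] = (0.55, 1.0)
    size_q: tuple[float, float] = (0.05, 0.95)
    gc_q: tuple[float, float] = (0.05, 0.95)
    regions: tuple[str, ...] | None = None
    with_decoy: bool = True
    decoy_noise_frac: float = 0.25


@dataclass
class SyntheticSpec:
    """Study-condition parameters of the generator.

    Defaults emulate a desk-scale version of a 16-region developmental
    brain panel: 2,000 genes over 64 samples laid out as 4 regions x 8
    stages x 2 sexes.  Feature marginals: log-normal abundance (median
    ~2 RPKM), log-normal gDNA size (median ~20 kb), GC content
    beta(2.5, 2.5) scaled to (25, 75)%.  Confound strengths are the
    loadings' scale on the three feature-tied shared factors; noise_sd is
    the per-gene residual sd on the log scale.
    """

    n_genes: int = 2000
    n_regions: int = 4
    n_stages: int = 8
    n_sexes: int = 2
    abundance_log_mean: float = 0.7
    abundance_log_sd: float = 1.2
    gdna_log_mean: float = math.log(2.0e4)
    gdna_log_sd: float = 1.1
    gc_beta_a: float = 2.5
    gc_beta_b: float = 2.5
    gc_range: tuple[float, float] = (25.0, 75.0)
    confound_abundance: float = 0.40
    confound_size: float = 0.30
    confound_gc: float = 0.25
    noise_sd: float = 0.40
    modules: tuple[ModuleSpec, ...] = ()
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_regions * self.n_stages * self.n_sexes

    def validate(self) -> None:
        if self.n_genes < 10:
            raise MgcaDataError("n_genes must be >= 10")
        if self.n_samples < 2:
            raise MgcaDataError("need at least 2 samples")
        for m in self.modules:
            need = m.size * (2 if m.with_decoy else 1)
            if need > self.n_genes // 2:
                raise MgcaDataError(
                    f"module of size {m.size} (plus decoys) too large for "
                    f"{self.n_genes} genes"
                )
            if not (0.0 <= m.target_cc < 1.0):
                raise MgcaDataError("module target_cc must be in [0, 1)")
        if self.noise_sd <= 0:
            raise MgcaDataError("noise_sd must be positive")


@dataclass
class SyntheticData:
    """Generator output: matrix, features, and ground-truth gene sets."""

    expression: ExpressionMatrix
    features: GeneFeatureTable
    modules: list[GeneSet]
    decoys: list[GeneSet]
    spec: SyntheticSpec


def _sample_grid(spec: SyntheticSpec) -> pd.DataFrame:
    regions = [f"R{i + 1}" for i in range(spec.n_regions)]
    stages = [f"S{i + 1}" for i in range(spec.n_stages)]
    sexes = ["M", "F"][: spec.n_sexes]
    rows = [
        {"sample_id": f"{r}.{st}.{sx}", "region": r, "stage": st, "sex": sx}
        for r in regions
        for st in stages
        for sx in sexes
    ]
    return pd.DataFrame(rows)


def _truncated_quantile_draw(
    rng: np.random.Generator, n: int, window: tuple[float, float]
) -> np.ndarray:
    lo, hi = window
    if not (0.0 <= lo < hi <= 1.0):
        raise MgcaDataError("quantile window must satisfy 0 <= lo < hi <= 1")
    return rng.uniform(lo, hi, size=n)


def _loadings(
    spec: SyntheticSpec,
    q_abundance: np.ndarray,
    q_size: np.ndarray,
    q_gc: np.ndarray,
) -> np.ndarray:
    """Gene loadings on the three feature-tied shared factors.

    Smooth shapes of the feature quantiles mirroring the qualitative
    patterns of bulk brain co-expression: a bell in abundance centred in
    the upper-middle of the range (mid-to-highly expressed genes
    co-express most; the peak sits at the middle of the post-filter axis,
    where seed-abundance filtering typically retains the upper half),
    increasing in gDNA size, decreasing in GC content.
    """
    l1 = spec.confound_abundance * np.exp(-((q_abundance - 0.75) ** 2) / (2 * 0.15**2))
    l2 = spec.confound_size * q_size
    l3 = spec.confound_gc * (1.0 - q_gc)
    return np.column_stack([l1, l2, l3])


def _orthonormalize(cols: np.ndarray) -> np.ndarray:
    """Mean-center columns and Gram-Schmidt them to exact unit sample variance.

    Order-preserving (QR), so a region-masked module factor is only cleaned
    of the factors before it.  Returned columns q satisfy mean(q) = 0,
    var(q) = 1 (ddof 0) and exactly zero mutual sample covariance.
    """
    x = cols - cols.mean(axis=0)
    q, r = np.linalg.qr(x)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    return q * math.sqrt(x.shape[0])


def _module_loading_sq(
    spec: SyntheticSpec, member_load: np.ndarray, target_cc: float
) -> float:
    """Private-factor loading^2 giving the module its target raw-scale CC.

    For jointly Gaussian log-expression with common variance v and latent
    correlation rho, the raw-scale (log-normal) Pearson correlation is
    (exp(rho*v) - 1)/(exp(v) - 1).  We invert that attenuation, then solve
    the latent-scale balance

        rho = (c_cross + m^2) / (v_conf + m^2 + sigma^2),

    where c_cross is the mean cross-product of member confound loadings
    and v_conf their mean squared norm, iterating because v depends on
    m^2.  Clipped at zero when the confound alone overshoots the target.
    """
    if target_cc <= 0.0:
        return 0.0
    mean_load = member_load.mean(axis=0)
    c_cross = float(mean_load @ mean_load)
    v_conf = float((member_load**2).sum(axis=1).mean())
    s2 = spec.noise_sd**2
    m2 = 0.0
    for _ in range(50):
        v_tot = v_conf + m2 + s2
        rho_lat = math.log1p(target_cc * math.expm1(v_tot)) / v_tot
        if rho_lat >= 1.0:
            raise MgcaDataError("module target_cc unattainable at this noise level")
        m2_new = max((rho_lat * (v_conf + s2) - c_cross) / (1.0 - rho_lat), 0.0)
        if abs(m2_new - m2) < 1e-12:
            m2 = m2_new
            break
        m2 = m2_new
    return m2


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Draw one synthetic dataset from the spec (bit-reproducible per seed)."""
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(0,)))
    g, s = spec.n_genes, spec.n_samples
    samples = _sample_grid(spec)

    # --- features ------------------------------------------------------
    log_abund = rng.normal(spec.abundance_log_mean, spec.abundance_log_sd, g)
    log_size = rng.normal(spec.gdna_log_mean, spec.gdna_log_sd, g)
    gc_unit = rng.beta(spec.gc_beta_a, spec.gc_beta_b, g)

    # overwrite module member (and decoy twin) features with profile draws
    module_idx: list[np.ndarray] = []
    decoy_idx: list[np.ndarray] = []
    cursor = 0
    for m in spec.modules:
        mi = np.arange(cursor, cursor + m.size)
        cursor += m.size
        qa = _truncated_quantile_draw(rng, m.size, m.abundance_q)
        qs = _truncated_quantile_draw(rng, m.size, m.size_q)
        qg = _truncated_quantile_draw(rng, m.size, m.gc_q)
        log_abund[mi] = spec.abundance_log_mean + spec.abundance_log_sd * _st.norm.ppf(qa)
        log_size[mi] = spec.gdna_log_mean + spec.gdna_log_sd * _st.norm.ppf(qs)
        gc_unit[mi] = _st.beta.ppf(qg, spec.gc_beta_a, spec.gc_beta_b)
        module_idx.append(mi)
        if m.with_decoy:
            di = np.arange(cursor, cursor + m.size)
            cursor += m.size
            # feature twins: tiny jitter keeps ranks adjacent to the member's
            log_abund[di] = log_abund[mi] + rng.normal(0.0, 0.01, m.size)
            log_size[di] = log_size[mi] + rng.normal(0.0, 0.01, m.size)
            gc_unit[di] = np.clip(gc_unit[mi] + rng.normal(0.0, 0.002, m.size), 0.01, 0.99)
            decoy_idx.append(di)
        else:
            decoy_idx.append(np.array([], dtype=int))

    abundance = np.exp(log_abund)
    gdna = np.maximum(np.exp(log_size), 200.0).round()
    lo, hi = spec.gc_range
    gc = lo + (hi - lo) * gc_unit

    gene_ids = [f"G{i:05d}" for i in range(g)]
    features = GeneFeatureTable.from_columns(gene_ids, abundance, gdna, gc)

    # --- expression ----------------------------------------------------
    # quantiles within the realized genome, so loadings track the ranks
    # the analysis will actually use
    q_a = (np.argsort(np.argsort(abundance)) + 0.5) / g
    q_s = (np.argsort(np.argsort(gdna)) + 0.5) / g
    q_g = (np.argsort(np.argsort(gc)) + 0.5) / g
    load = _loadings(spec, q_a, q_s, q_g)

    # Raw factor draws, region masks applied to module factors before the
    # in-sample orthonormalization (see _orthonormalize): factors then have
    # exactly unit sample variance and zero mutual sample covariance, and
    # residual noise is projected off the factor span, so the realized
    # covariance structure is the stated one and background genes carry no
    # incidental in-sample loading on a module's private factor.
    raw_cols = [rng.normal(size=s) for _ in range(3)]
    for m in spec.modules:
        h = rng.normal(size=s)
        if m.regions is not None:
            active = samples["region"].isin(m.regions).to_numpy()
            if active.sum() < 3:
                raise MgcaDataError("module regions select fewer than 3 samples")
            h = h * active
        raw_cols.append(h)
    basis = _orthonormalize(np.column_stack(raw_cols))  # (s, 3 + n_modules)
    factors = basis[:, :3].T

    z = load @ factors
    for j, (m, mi) in enumerate(zip(spec.modules, module_idx)):
        m_load = math.sqrt(_module_loading_sq(spec, load[mi], m.target_cc))
        z[mi] += m_load * basis[:, 3 + j][None, :]

    eps = rng.normal(size=(g, s))
    eps -= (eps @ basis) @ basis.T / s  # in-sample orthogonal to all factors
    noise_scale = np.full(g, spec.noise_sd)
    for m, di in zip(spec.modules, decoy_idx):
        if di.size:
            noise_scale[di] = spec.noise_sd * m.decoy_noise_frac
    z += noise_scale[:, None] * eps
    expz = np.exp(z)
    values = abundance[:, None] * expz / expz.mean(axis=1, keepdims=True)

    expression = ExpressionMatrix(gene_ids, values, samples)
    modules = [
        GeneSet(f"module{j + 1}", [gene_ids[i] for i in mi])
        for j, mi in enumerate(module_idx)
    ]
    decoys = [
        GeneSet(f"decoy{j + 1}", [gene_ids[i] for i in di])
        for j, di in enumerate(decoy_idx)
        if di.size
    ]
    return SyntheticData(expression, features, modules, decoys, spec)


def make_confounded_decoy(
    features: GeneFeatureTable,
    seed_set: GeneSet,
    rng: np.random.Generator,
    window: int = 50,
    forbidden: frozenset[str] = frozenset(),
) -> GeneSet:
    """Draw a set feature-matched to the seed set on all three features.

    For each seed gene, a match is drawn uniformly from genes lying within
    +/- window ranks of it on *every* feature simultaneously, excluding the
    seed set, ``forbidden`` genes (e.g. planted module members) and genes
    already chosen.  On generator output this pool contains each module
    gene's planted twin; on arbitrary data joint matching may be
    infeasible, which raises an error.
    """
    from .features import rank_genes

    ranked = {name: rank_genes(features, name) for name in
              ("abundance", "gdna_size", "gc_content")}
    blocked = set(seed_set.gene_ids) | set(forbidden)
    chosen: list[str] = []
    taken: set[str] = set()
    for gseed in seed_set:
        pools = []
        for rl in ranked.values():
            pools.append({rl.gene_at(r) for r in rl.window_ranks(gseed, window)})
        cands = sorted(set.intersection(*pools) - blocked - taken - {gseed})
        if not cands:
            raise MgcaDataError(
                f"no jointly feature-matched candidate for {gseed!r} within "
                f"+/-{window} ranks on all three features"
            )
        pick = cands[int(rng.integers(0, len(cands)))]
        chosen.append(pick)
        taken.add(pick)
    return GeneSet(f"decoy({seed_set.name})", chosen)
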