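"""Synthetic study generator with known ground truth.

Emulates a small post-mortem brain case-control bulk RNA-seq design:
7 case / 8 comparison subjects, each sampled in four regions (two of
them highly correlated cortical areas), negative-binomial counts with
planted diagnosis effects, demographic covariates, planted enriched
gene sets, cell-type mixtures and a partner-study DEG table.  Every
generator is deterministic under its seed, so each downstream stage of
the pipeline can be tested against recorded truth without any external
download.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LN2 = np.log(2.0)

#: broad cell types used throughout; medium spiny neurons are striatal-only,
#: excitatory (pyramidal) neurons cortical-only.
CELL_TYPES = (
    "excitatory_neuron",
    "medium_spiny_neuron",
    "interneuron",
    "astrocyte",
    "oligodendrocyte",
    "ependymal",
    "immune",
    "vascular",
)


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of the emulated case-control study.

    Defaults mirror the study design: 7 cases vs 8 comparison subjects,
    four brain regions of which BA11/BA47 form a correlated cortical
    pair, ~15k genes after QC, planted differential expression
    concentrated in the striatal regions, and ~40M-read libraries.
    """

    n_cases: int = 7
    n_controls: int = 8
    regions: tuple[str, ...] = ("BA11", "BA47", "caudate", "NAcc")
    cortical_regions: tuple[str, ...] = ("BA11", "BA47")
    n_genes: int = 15000
    n_de_global: int = 900
    n_de_regional: dict[str, int] = field(
        default_factory=lambda: {"caudate": 30, "NAcc": 200}
    )
    de_log2fc: float = 1.0
    baseline_log2_mean: float = 2.0
    baseline_log2_sd: float = 3.2
    cortical_corr: float = 0.7
    between_region_corr: float = 0.2
    dispersion: float = 0.1
    bio_sd: float = 0.25  # per-sample biological noise, log2 units
    lib_size_range: tuple[float, float] = (20_000_000, 40_000_000)
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "pH": 0.3}
    )
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls) < 0 or self.n_genes < 0:
            raise ValueError("counts must be nonnegative")
        if not 0.0 <= self.cortical_corr <= 1.0:
            raise ValueError("cortical_corr must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        n_planted = self.n_de_global + sum(self.n_de_regional.values())
        if self.n_de_global > self.n_genes or n_planted > self.n_genes:
            raise ValueError(
                f"planted DE genes ({n_planted}) exceed n_genes ({self.n_genes})"
            )
        for r in self.n_de_regional:
            if r not in self.regions:
                raise ValueError(f"n_de_regional names unknown region {r!r}")
        for r in self.cortical_regions:
            if r not in self.regions:
                raise ValueError(f"cortical region {r!r} not in regions")


@dataclass
class GroundTruth:
    """Record of every planted effect, keyed the way the pipeline reports."""

    universe: tuple[str, ...]
    de_genes: dict[str, dict[str, float]]  # scope -> {gene: signed log2 effect}
    enriched_sets: set[str] = field(default_factory=set)
    enriched_set_bias: dict[str, float] = field(default_factory=dict)
    true_fractions: pd.DataFrame | None = None
    partner_shared: set[str] = field(default_factory=set)

    def all_de(self) -> dict[str, float]:
        """Union of planted effects over scopes (global wins on clash)."""
        merged: dict[str, float] = {}
        for scope in sorted(self.de_genes):
            merged.update(self.de_genes[scope])
        merged.update(self.de_genes.get("global", {}))
        return merged


# ---------------------------------------------------------------------------
# counts + metadata

# Table-style demographic summaries used as sampling means/SDs
# (age yr, PMI h, pH, RIN): (case_mean, case_sd, control_mean, control_sd)
_COVARIATE_SUMMARIES = {
    "age": (47.4, 14.7, 47.6, 13.4),
    "PMI": (17.8, 8.3, 15.2, 4.4),
    "pH": (6.7, 0.15, 6.6, 0.14),
    "RIN": (7.8, 0.44, 7.6, 0.65),
}


def _make_metadata(cfg: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    subjects = [f"case{i + 1:02d}" for i in range(cfg.n_cases)] + [
        f"ctrl{i + 1:02d}" for i in range(cfg.n_controls)
    ]
    dx = ["case"] * cfg.n_cases + ["comparison"] * cfg.n_controls
    # sex-matched design: alternate within each group
    sexes = [("M" if i % 2 == 0 else "F") for i in range(cfg.n_cases)] + [
        ("M" if i % 2 == 0 else "F") for i in range(cfg.n_controls)
    ]
    covs = {}
    for name, (m1, s1, m0, s0) in _COVARIATE_SUMMARIES.items():
        vals = np.where(
            np.array(dx) == "case",
            rng.normal(m1, s1, len(subjects)),
            rng.normal(m0, s0, len(subjects)),
        )
        if name == "age":
            vals = np.clip(vals, 20, 69)
        elif name == "PMI":
            vals = np.clip(vals, 2, None)
        elif name == "RIN":
            vals = np.clip(vals, 5.5, 10)
        covs[name] = np.round(vals, 2)

    rows = []
    for j, subj in enumerate(subjects):
        for region in cfg.regions:
            rows.append(
                {
                    "sample": f"{subj}_{region}",
                    "subject": subj,
                    "region": region,
                    "diagnosis": dx[j],
                    "sex": sexes[j],
                    "age": covs["age"][j],
                    "PMI": covs["PMI"][j],
                    "pH": covs["pH"][j],
                    "RIN": covs["RIN"][j],
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def generate_study(
    config: StudyConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate counts, sample metadata and ground truth.

    Counts follow a negative-binomial model: gene baselines are drawn
    log-normal, per-sample library sizes uniform over
    ``lib_size_range``, and the log2 mean is shifted by the planted
    diagnosis effect, linear covariate effects (sex, pH), a shared
    subject-level latent inducing modest correlation between every
    region pair, and an extra cortical latent calibrated so the
    consensus correlation of the cortical pair is ~``cortical_corr``.

    Returns ``(counts, metadata, truth)`` with counts as a gene x sample
    integer DataFrame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _make_metadata(config, rng)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    n_samples = len(meta)

    # gene relative abundance (log-normal baseline; the heavy left tail
    # yields genes below the CPM floor, as in real libraries)
    base_log2 = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    prop = 2.0**base_log2
    prop /= prop.sum()
    lib = rng.uniform(*config.lib_size_range, n_samples)

    # planted diagnosis effects, disjoint gene picks per scope
    n_planted = config.n_de_global + sum(config.n_de_regional.values())
    picked = rng.choice(config.n_genes, size=n_planted, replace=False)
    de_genes: dict[str, dict[str, float]] = {}
    offset = 0
    scopes = [("global", config.n_de_global)] + sorted(config.n_de_regional.items())
    for scope, n_de in scopes:
        idx = picked[offset : offset + n_de]
        offset += n_de
        signs = rng.choice([-1.0, 1.0], size=n_de)
        de_genes[scope] = {genes[i]: s * config.de_log2fc for i, s in zip(idx, signs)}

    # noise budget on the log2 scale: biological + counting noise.
    # Counting-noise variance per gene ~ (1/mu + dispersion)/ln(2)^2;
    # averaged over genes that would pass a CPM>=1 filter, it sets the
    # shared-latent variances needed to hit the target correlations.
    mu_typ = prop * lib.mean()
    expressed = mu_typ >= lib.mean() * 1e-6  # ~CPM >= 1
    v_nb = (1.0 / np.maximum(mu_typ[expressed], 1e-9) + config.dispersion) / LN2**2
    v_ind = config.bio_sd**2 + float(np.mean(v_nb))
    bc = min(config.between_region_corr, 0.99)
    cc = min(config.cortical_corr, 0.99)
    v_glob = bc / (1.0 - bc) * v_ind
    v_cort = max(cc / (1.0 - cc) * v_ind - v_glob, 0.0)

    u_glob = rng.normal(0.0, np.sqrt(v_glob), (len(meta["subject"].unique()), config.n_genes))
    u_cort = rng.normal(0.0, np.sqrt(v_cort), u_glob.shape)
    subj_index = {s: i for i, s in enumerate(meta["subject"].unique())}

    # per-gene covariate coefficients (linear on log2 scale)
    z_cov = {}
    coef = {}
    for cov, eff in config.covariate_effect_sizes.items():
        if eff == 0:
            continue
        vals = (
            (meta[cov] == "M").astype(float).to_numpy()
            if cov == "sex"
            else meta[cov].to_numpy(dtype=float)
        )
        sd = vals.std()
        z_cov[cov] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        coef[cov] = rng.normal(0.0, eff, config.n_genes)

    eff_global = np.zeros(config.n_genes)
    for g, e in de_genes["global"].items():
        eff_global[int(g[1:])] = e
    eff_regional = {r: np.zeros(config.n_genes) for r in config.n_de_regional}
    for r in config.n_de_regional:
        for g, e in de_genes[r].items():
            eff_regional[r][int(g[1:])] = e

    counts = np.empty((config.n_genes, n_samples), dtype=np.int64)
    is_case = (meta["diagnosis"] == "case").to_numpy()
    r_nb = 1.0 / config.dispersion
    for s in range(n_samples):
        region = meta["region"].iloc[s]
        subj = subj_index[meta["subject"].iloc[s]]
        delta = u_glob[subj] + rng.normal(0.0, config.bio_sd, config.n_genes)
        if region in config.cortical_regions:
            delta = delta + u_cort[subj]
        if is_case[s]:
            delta = delta + eff_global
            if region in eff_regional:
                delta = delta + eff_regional[region]
        for cov in coef:
            delta = delta + coef[cov] * z_cov[cov][s]
        mu = lib[s] * prop * 2.0**delta
        counts[:, s] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))

    counts_df = pd.DataFrame(counts, index=genes, columns=meta.index)
    truth = GroundTruth(universe=tuple(genes), de_genes=de_genes)
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# gene sets


def generate_genesets(
    universe,
    n_sets: int,
    set_size_range: tuple[int, int],
    n_planted: int,
    truth: GroundTruth,
    seed: int,
    down_bias: float = 0.8,
    planted_de_frac: float = 0.7,
    name_prefix: str = "",
):
    """Draw gene sets, ``n_planted`` of them enriched for planted DE genes.

    Planted sets take ``planted_de_frac`` of their members from the
    truth DE genes, each drawn from the downregulated pool with
    probability ``down_bias`` (1.0 forces a purely downregulated
    overlap); the remainder, and all non-planted sets, are uniform draws
    from the universe.  Returns a :class:`~braintx.enrichment.GeneSetCollection`
    and records the planted set names in ``truth.enriched_sets``.
    """
    from .enrichment import GeneSetCollection

    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed universe size")
    if n_planted > n_sets:
        raise ValueError("n_planted exceeds n_sets")
    rng = np.random.default_rng(seed)

    effects = truth.all_de()
    down = sorted(g for g, e in effects.items() if e < 0)
    up = sorted(g for g, e in effects.items() if e > 0)

    sets: dict[str, tuple[str, ...]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        planted = i < n_planted
        members: list[str] = []
        if planted:
            n_de = int(round(planted_de_frac * size))
            d_pool, u_pool = list(down), list(up)
            for _ in range(n_de):
                pool = d_pool if (rng.random() < down_bias and d_pool) else u_pool
                if not pool:
                    pool = d_pool or u_pool
                if not pool:
                    break
                j = int(rng.integers(len(pool)))
                members.append(pool.pop(j))
        # filler: uniform from the universe; planted sets avoid DE genes so
        # their DE overlap is exactly the members drawn above
        pool_fill = [g for g in universe if g not in effects] if planted else universe
        fill = rng.permutation(len(pool_fill))
        chosen = set(members)
        for j in fill:
            if len(members) >= size:
                break
            g = pool_fill[j]
            if g not in chosen:
                members.append(g)
                chosen.add(g)
        name = (
            f"{name_prefix}PLANTED_SET_{i + 1:03d}"
            if planted
            else f"{name_prefix}RANDOM_SET_{i + 1:03d}"
        )
        sets[name] = tuple(members)
        if planted:
            truth.enriched_sets.add(name)
            truth.enriched_set_bias[name] = down_bias
    return GeneSetCollection(sets=sets, source="synthetic")


# ---------------------------------------------------------------------------
# cell-type reference, fractions and mixtures


def generate_reference(
    cell_types=CELL_TYPES,
    n_genes: int = 400,
    n_markers_per_type: int = 20,
    marker_fold: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Synthetic cell-type reference (type x gene mean expression, linear).

    Each type gets ``n_markers_per_type`` planted marker genes expressed
    ``marker_fold``-fold above all other types.  Returns the reference
    table and the planted marker map.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    # shared per-gene baseline with mild type-specific variation, so marker
    # ratios are dominated by the planted fold change
    gene_base = rng.lognormal(mean=2.0, sigma=0.8, size=n_genes)
    type_noise = rng.lognormal(mean=0.0, sigma=0.2, size=(len(cell_types), n_genes))
    base = gene_base[None, :] * type_noise
    markers: dict[str, list[str]] = {}
    pos = 0
    for t, ct in enumerate(cell_types):
        idx = list(range(pos, pos + n_markers_per_type))
        pos += n_markers_per_type
        base[:, idx] *= 0.5
        base[t, idx] *= 2.0 * marker_fold
        markers[ct] = [genes[i] for i in idx]
    return pd.DataFrame(base, index=list(cell_types), columns=genes), markers


def generate_fractions(
    meta: pd.DataFrame,
    cell_types=CELL_TYPES,
    shift_type: str = "medium_spiny_neuron",
    shift: float = -0.08,
    concentration: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet cell-type fractions per sample with a diagnosis shift.

    ``shift`` moves the mean fraction of ``shift_type`` in cases (on the
    fraction scale); rows renormalize to 1.  Region-inappropriate types
    (MSN in cortex, excitatory neurons in striatum) get fraction 0.
    """
    rng = np.random.default_rng(seed)
    cell_types = list(cell_types)
    base = np.array([0.18, 0.22, 0.08, 0.18, 0.15, 0.04, 0.05, 0.10])[: len(cell_types)]
    base = base / base.sum()
    rows = {}
    for sample, row in meta.iterrows():
        mean = base.copy()
        if row["diagnosis"] == "case" and shift_type in cell_types:
            # shift the target type's mean and rescale the others so the
            # planted shift survives the sum-to-one constraint
            j = cell_types.index(shift_type)
            new = max(mean[j] + shift, 1e-3)
            others = mean.sum() - mean[j]
            mean *= (1.0 - new) / others
            mean[j] = new
        region = str(row["region"])
        cortical = region in ("BA11", "BA47", "OFC") or "OFC" in region
        zero = "medium_spiny_neuron" if cortical else "excitatory_neuron"
        if zero in cell_types:
            mean[cell_types.index(zero)] = 0.0
        alive = mean > 0
        f = np.zeros(len(cell_types))
        f[alive] = rng.dirichlet(concentration * mean[alive] / mean[alive].sum())
        rows[sample] = f
    return pd.DataFrame.from_dict(rows, orient="index", columns=cell_types)


def generate_mixtures(
    signature: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk expression as the fraction-weighted sum of signature columns.

    ``bulk[g, s] = sum_k fractions[s, k] * signature[g, k]`` plus
    Gaussian noise truncated at zero.  ``signature`` is gene x type
    (linear scale), ``fractions`` sample x type with rows summing to 1.
    """
    if (fractions.to_numpy() < 0).any():
        raise ValueError("fractions must be nonnegative")
    sums = fractions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ValueError("fraction rows must sum to 1")
    if list(fractions.columns) != list(signature.columns):
        missing = set(signature.columns) ^ set(fractions.columns)
        raise ValueError(f"cell types disagree between fractions and signature: {missing}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    bulk = signature.to_numpy() @ fractions.to_numpy().T
    if noise_sd > 0:
        bulk = bulk + rng.normal(0.0, noise_sd, bulk.shape)
    return pd.DataFrame(
        np.maximum(bulk, 0.0), index=signature.index, columns=fractions.index
    )


# ---------------------------------------------------------------------------
# partner study


def generate_partner_study(
    truth: GroundTruth,
    overlap_frac: float,
    sign_agreement: float,
    n_report: int,
    seed: int,
) -> pd.DataFrame:
    """DEG table of an external study sharing part of the planted truth.

    ``overlap_frac`` of the reported genes are planted DE genes whose
    log2FC sign agrees with the truth with probability
    ``sign_agreement``; the rest are null genes with small noise
    effects.  All reported p-values are below 0.01, matching the
    convention of publishing only nominally significant genes.
    """
    if not 0.0 <= overlap_frac <= 1.0 or not 0.0 <= sign_agreement <= 1.0:
        raise ValueError("overlap_frac and sign_agreement must lie in [0, 1]")
    if n_report > len(truth.universe):
        raise ValueError("n_report exceeds the gene universe")
    rng = np.random.default_rng(seed)
    effects = truth.all_de()
    de_pool = sorted(effects)
    n_shared = min(int(round(overlap_frac * n_report)), len(de_pool))
    shared = list(rng.choice(de_pool, size=n_shared, replace=False))
    null_pool = sorted(set(truth.universe) - set(de_pool))
    others = list(rng.choice(null_pool, size=n_report - n_shared, replace=False))

    rows = []
    for g in shared:
        sign = np.sign(effects[g])
        if rng.random() > sign_agreement:
            sign = -sign
        mag = abs(rng.normal(abs(effects[g]), 0.3)) + 0.05
        rows.append((g, sign * mag))
    for g in others:
        rows.append((g, rng.normal(0.0, 0.5)))
    table = pd.DataFrame(rows, columns=["gene", "log2FC"])
    table["p"] = rng.uniform(1e-6, 0.01, len(table))
    truth.partner_shared = set(shared)
    return table.set_index("gene")
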