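"""Seeded synthetic inputs for every pipeline stage, with ground truth.

Three generators emulate the data the analysis consumes:

* :func:`gen_nuclear_field` -- two-channel (DAPI + immunomarker) 8-bit
  microscopy fields of non-overlapping elliptical nuclei, with a labelled
  truth mask.  Four experimental groups differ in marker mean intensity and
  speckle texture; groups 2 and 3 are configured identically by default
  (cytokine vs cytokine+polybrene), mirroring the biology where polybrene
  adds no detectable nuclear-pattern effect.
* :func:`gen_methylation_dataset` -- probe-level M/U intensity tables for a
  27k-style methylation array (two CpG probes per gene: promoter and first
  exon), with planted median-beta shifts and a clustered chromosomal region,
  plus a truth ledger of every planted differential gene.
* :func:`gen_medip_tags` -- per-group log2 MeDIP enrichment ratios for a set
  of array tags in which three groups share a configurable small
  intersection.

All generators are deterministic given (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageFieldConfig",
    "MethylationSimConfig",
    "PlantedChange",
    "ClusteredRegion",
    "TagSimConfig",
    "gen_nuclear_field",
    "gen_methylation_dataset",
    "gen_medip_tags",
    "image_config_for_group",
    "default_methylation_config",
    "design_for",
    "default_tag_config",
    "tag_section_probabilities",
]

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
ALLOSOMES = ("chrX", "chrY")
CHROMOSOMES = AUTOSOMES + ALLOSOMES


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


# --------------------------------------------------------------------------
# imaging fields
# --------------------------------------------------------------------------

#: Per-group marker appearance: (mean intensity, speckle texture scale).
#: Groups 2 and 3 are deliberately identical; group 4 differs in both mean
#: and texture so that no single parameter separates all four groups.
GROUP_MARKER_DEFAULTS = {
    1: (60.0, 0.4),
    2: (140.0, 1.2),
    3: (140.0, 1.2),
    4: (185.0, 3.0),
}


@dataclass(frozen=True)
class ImageFieldConfig:
    """One synthetic two-channel field of nuclei for a single cell group."""

    group_id: int
    marker_mean: float
    marker_texture_scale: float = 1.0
    field_size: int = 512
    n_nuclei: int = 80
    nucleus_radius_range: tuple[float, float] = (8.0, 14.0)
    background_level: float = 10.0
    noise_sd: float = 3.0
    dapi_level: float = 170.0
    seed: int = 0

    def validate(self) -> None:
        if self.group_id not in (1, 2, 3, 4):
            raise ConfigError(f"group_id must be 1-4, got {self.group_id}")
        if self.n_nuclei < 1:
            raise ConfigError("n_nuclei must be >= 1")
        lo, hi = self.nucleus_radius_range
        if not (0 < lo <= hi):
            raise ConfigError("nucleus_radius_range must satisfy 0 < lo <= hi")
        if self.noise_sd < 0 or self.marker_texture_scale < 0:
            raise ConfigError("noise_sd and marker_texture_scale must be >= 0")
        for v in (self.marker_mean, self.background_level, self.dapi_level):
            if not 0 <= v <= 255:
                raise ConfigError("intensity levels must lie in [0, 255]")


def image_config_for_group(group_id: int, seed: int = 0, **overrides) -> ImageFieldConfig:
    """Default field config for one of the four experimental groups."""
    mean, tex = GROUP_MARKER_DEFAULTS[group_id]
    kw = dict(group_id=group_id, marker_mean=mean, marker_texture_scale=tex, seed=seed)
    kw.update(overrides)
    return ImageFieldConfig(**kw)


def _place_ellipses(cfg: ImageFieldConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping ellipses fully inside the field."""
    lo, hi = cfg.nucleus_radius_range
    placed = []  # (row, col, a, b, theta)
    max_tries = 200 * cfg.n_nuclei
    tries = 0
    while len(placed) < cfg.n_nuclei:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {cfg.n_nuclei} non-overlapping nuclei of radius "
                f"{lo}-{hi} px in a {cfg.field_size}x{cfg.field_size} px field "
                f"after {max_tries} tries; reduce n_nuclei or the radius range"
            )
        tries += 1
        a = rng.uniform(lo, hi)                      # major semi-axis
        b = a * rng.uniform(0.6, 0.95)               # bounded eccentricity
        theta = rng.uniform(-np.pi / 2, np.pi / 2)
        margin = a + 2.0
        r = rng.uniform(margin, cfg.field_size - margin)
        c = rng.uniform(margin, cfg.field_size - margin)
        # conservative overlap check on bounding circles
        ok = all((r - r2) ** 2 + (c - c2) ** 2 > (a + a2 + 1.0) ** 2
                 for r2, c2, a2, _, _ in placed)
        if ok:
            placed.append((r, c, a, b, theta))
    return placed


def gen_nuclear_field(cfg: ImageFieldConfig):
    """Render one synthetic field.

    Returns
    -------
    dapi : (H, W) uint8
        Nuclear-stain channel used for segmentation.
    marker : (H, W) uint8
        Immunomarker channel; intensity and speckle texture depend on the
        group.
    truth : (H, W) uint16
        Label mask; label ``k`` marks nucleus ``k`` (background 0).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.field_size
    ellipses = _place_ellipses(cfg, rng)

    truth = np.zeros((n, n), dtype=np.uint16)
    rows, cols = np.mgrid[0:n, 0:n]
    for k, (r0, c0, a, b, theta) in enumerate(ellipses, start=1):
        ct, st = np.cos(theta), np.sin(theta)
        hw = int(np.ceil(a)) + 2
        rlo, rhi = max(int(r0) - hw, 0), min(int(r0) + hw + 1, n)
        clo, chi = max(int(c0) - hw, 0), min(int(c0) + hw + 1, n)
        rr = rows[rlo:rhi, clo:chi] - r0
        cc = cols[rlo:rhi, clo:chi] - c0
        u = rr * ct + cc * st
        v = -rr * st + cc * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        truth[rlo:rhi, clo:chi][inside] = k

    fg = truth > 0
    dapi = np.full((n, n), cfg.background_level, dtype=float)
    dapi[fg] = cfg.dapi_level

    marker = np.full((n, n), cfg.background_level, dtype=float)
    marker[fg] = cfg.marker_mean

    # speckle texture: small bright blobs inside nuclei; density scales with
    # the group's texture factor, so texture separates groups of equal mean
    if cfg.marker_texture_scale > 0:
        for k, (r0, c0, a, b, theta) in enumerate(ellipses, start=1):
            area = np.pi * a * b
            n_speckles = rng.poisson(cfg.marker_texture_scale * area / 60.0)
            for _ in range(n_speckles):
                sr = r0 + rng.normal(0, a / 2.5)
                sc = c0 + rng.normal(0, a / 2.5)
                amp = rng.uniform(25, 55)
                sig = rng.uniform(1.0, 2.0)
                hw = int(3 * sig) + 1
                rlo, rhi = int(sr) - hw, int(sr) + hw + 1
                clo, chi = int(sc) - hw, int(sc) + hw + 1
                rlo, clo = max(rlo, 0), max(clo, 0)
                rhi, chi = min(rhi, n), min(chi, n)
                if rlo >= rhi or clo >= chi:
                    continue
                rr = rows[rlo:rhi, clo:chi] - sr
                cc = cols[rlo:rhi, clo:chi] - sc
                blob = amp * np.exp(-(rr**2 + cc**2) / (2 * sig**2))
                region = truth[rlo:rhi, clo:chi] == k
                marker[rlo:rhi, clo:chi][region] += blob[region]

    if cfg.noise_sd > 0:
        dapi = dapi + rng.normal(0, cfg.noise_sd, size=dapi.shape)
        marker = marker + rng.normal(0, cfg.noise_sd, size=marker.shape)

    dapi = np.clip(np.rint(dapi), 0, 255).astype(np.uint8)
    marker = np.clip(np.rint(marker), 0, 255).astype(np.uint8)
    return dapi, marker, truth


# --------------------------------------------------------------------------
# methylation arrays
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedChange:
    """A set of genes whose group-``group_b`` betas are shifted vs ``group_a``."""

    genes: tuple[int, ...]          # gene indices
    group_a: int
    group_b: int
    delta: float                    # magnitude, >= 0.2 by convention
    direction: str                  # "gain" or "loss"

    def signed_delta(self) -> float:
        return self.delta if self.direction == "gain" else -self.delta


@dataclass(frozen=True)
class ClusteredRegion:
    """A run of consecutive genes on one chromosome carrying planted changes."""

    chrom: str
    start_index: int                # index of the first gene within the chromosome
    length: int                     # genes spanned by the region
    changed: tuple[int, ...]        # offsets (0..length-1) of the changed genes
    group_a: int
    group_b: int
    delta: float
    direction: str


@dataclass(frozen=True)
class MethylationSimConfig:
    n_genes: int = 2000
    probes_per_gene: int = 2        # promoter + first exon
    n_replicates: int = 3
    groups: tuple[int, ...] = (1, 2, 3, 4)
    # mixture of Beta distributions: (weight, a, b) -- unmethylated mode near
    # 0, methylated mode near 1, small intermediate component
    baseline_beta_distribution: tuple[tuple[float, float, float], ...] = (
        (0.60, 2.0, 18.0),
        (0.30, 18.0, 2.0),
        (0.10, 5.0, 5.0),
    )
    planted_changes: tuple[PlantedChange, ...] = ()
    clustered_regions: tuple[ClusteredRegion, ...] = ()
    sigma_beta: float = 0.05
    intensity_scale: float = 10_000.0
    detection_p_failure_rate: float = 0.01
    allosome_fraction: float = 0.05  # genes placed on chrX/chrY
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.probes_per_gene < 1 or self.n_replicates < 1:
            raise ConfigError("counts must be >= 1")
        w = sum(c[0] for c in self.baseline_beta_distribution)
        if abs(w - 1.0) > 1e-9:
            raise ConfigError("baseline mixture weights must sum to 1")
        if self.intensity_scale <= 100:
            raise ConfigError("intensity_scale must exceed the +100 beta offset")
        if not 0 <= self.detection_p_failure_rate <= 1:
            raise ConfigError("detection_p_failure_rate must be in [0, 1]")
        beta_max = (self.intensity_scale - 100.0) / self.intensity_scale
        for pc in self.planted_changes:
            if pc.direction not in ("gain", "loss"):
                raise ConfigError(f"direction must be gain/loss, got {pc.direction!r}")
            if pc.delta < 0:
                raise ConfigError("planted delta must be >= 0")
            if pc.delta > beta_max:
                raise ConfigError(
                    f"planted delta {pc.delta} cannot keep beta within "
                    f"[0, {beta_max:.4f}]"
                )
            for g in pc.genes:
                if not 0 <= g < self.n_genes:
                    raise ConfigError(f"planted gene index {g} out of range")
        for cr in self.clustered_regions:
            if cr.chrom not in CHROMOSOMES:
                raise ConfigError(f"unknown chromosome {cr.chrom!r}")
            if cr.chrom in ALLOSOMES:
                raise ConfigError("clustered regions must be autosomal")
            if any(o < 0 or o >= cr.length for o in cr.changed):
                raise ConfigError("clustered changed offsets must lie in the region")


def _chromosome_layout(cfg: MethylationSimConfig) -> pd.DataFrame:
    """Assign genes to chromosomes in contiguous position-ordered blocks."""
    n = cfg.n_genes
    n_allo = max(2, int(round(cfg.allosome_fraction * n)))
    n_y = max(1, n_allo // 5)
    n_x = n_allo - n_y
    n_auto = n - n_allo
    per = [n_auto // len(AUTOSOMES)] * len(AUTOSOMES)
    for i in range(n_auto - sum(per)):
        per[i] += 1
    counts = dict(zip(AUTOSOMES, per))
    counts["chrX"] = n_x
    counts["chrY"] = n_y
    rows = []
    gi = 0
    for chrom in CHROMOSOMES:
        for j in range(counts[chrom]):
            rows.append((gi, f"GENE{gi:05d}", chrom, 100_000 * (j + 1)))
            gi += 1
    return pd.DataFrame(rows, columns=["gene_index", "gene", "chrom", "pos"])


def _cluster_changes(cfg: MethylationSimConfig, layout: pd.DataFrame):
    """Expand clustered regions into PlantedChange records on real gene ids."""
    out = []
    for cr in cfg.clustered_regions:
        on_chrom = layout[layout.chrom == cr.chrom].reset_index(drop=True)
        if cr.start_index + cr.length > len(on_chrom):
            raise ConfigError(
                f"clustered region exceeds {cr.chrom} ({len(on_chrom)} genes)"
            )
        genes = tuple(
            int(on_chrom.gene_index.iloc[cr.start_index + o]) for o in cr.changed
        )
        out.append(
            PlantedChange(genes, cr.group_a, cr.group_b, cr.delta, cr.direction)
        )
    return out


def autosomal_gene_indices(cfg: MethylationSimConfig) -> np.ndarray:
    """Gene indices on autosomes (eligible for planted differential calls)."""
    layout = _chromosome_layout(cfg)
    return layout.loc[~layout.chrom.isin(ALLOSOMES), "gene_index"].to_numpy()


def default_methylation_config(seed: int = 0, n_genes: int = 2000) -> MethylationSimConfig:
    """The four-group study design at desk scale.

    Effect structure (gene counts scaled ~1:10 from a full 14k-gene array):
    cytokine stimulation (group 2) produces balanced gains and losses;
    polybrene (group 3) is near-null; lentiviral transduction (group 4)
    produces many changes, overwhelmingly gains.  A clustered region on chr6
    (a histone-gene-like cluster) is changed in both the group-2 and group-4
    contrasts, with a higher changed fraction in the group-4 contrast.
    """
    rng = np.random.default_rng(seed + 104_729)
    probe = MethylationSimConfig(n_genes=n_genes, seed=seed)
    layout = _chromosome_layout(probe)
    auto = layout[~layout.chrom.isin(ALLOSOMES)]
    chr6 = auto[auto.chrom == "chr6"].reset_index(drop=True)

    cluster_len = 16
    if len(chr6) < cluster_len:
        raise ConfigError(
            f"n_genes={n_genes} leaves only {len(chr6)} genes on chr6; "
            f"the clustered region needs {cluster_len}"
        )
    cluster_start = min(10, len(chr6) - cluster_len)
    # offsets changed in each contrast; the 1v4 set contains the 1v2 set and
    # is denser, so the same region carries a higher changed fraction in the
    # transduced contrast
    offs_1v2 = (0, 3, 6, 9, 12, 15)
    offs_1v4 = (0, 1, 3, 4, 5, 6, 7, 9, 10, 11, 12, 14, 15)
    cluster_gene_idx = {
        int(chr6.gene_index.iloc[cluster_start + o]) for o in range(cluster_len)
    }

    pool = [int(g) for g in auto.gene_index if g not in cluster_gene_idx]
    rng.shuffle(pool)

    def take(k):
        out, pool[:] = pool[:k], pool[k:]
        return tuple(sorted(out))

    planted = (
        PlantedChange(take(11), 1, 2, 0.30, "gain"),
        PlantedChange(take(13), 1, 2, 0.30, "loss"),
        PlantedChange(take(1), 1, 3, 0.25, "gain"),
        PlantedChange(take(1), 1, 3, 0.25, "loss"),
        PlantedChange(take(75), 1, 4, 0.30, "gain"),
        PlantedChange(take(10), 1, 4, 0.30, "loss"),
    )
    clusters = (
        ClusteredRegion("chr6", cluster_start, cluster_len, offs_1v2, 1, 2, 0.30, "gain"),
        ClusteredRegion("chr6", cluster_start, cluster_len, offs_1v4, 1, 4, 0.30, "gain"),
    )
    return MethylationSimConfig(
        n_genes=n_genes,
        planted_changes=planted,
        clustered_regions=clusters,
        seed=seed,
    )


def gen_methylation_dataset(cfg: MethylationSimConfig):
    """Simulate a probe-level intensity table plus its truth ledger.

    The per-probe intended beta ``b`` is converted to intensities with a
    fixed total signal ``s = M + U + 100``: ``M = b*s`` and ``U = s - 100 - M``,
    so the downstream beta formula ``M / (M + U + 100)`` recovers ``b``
    exactly in the noise-free case.

    Returns
    -------
    probe_table : DataFrame
        Long format: probe_id, gene, chrom, pos, sample_id, M, U, detection_p.
    truth : DataFrame
        One row per planted differential gene and contrast: gene, chrom,
        group_a, group_b, delta, direction, clustered.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    layout = _chromosome_layout(cfg)
    all_changes = list(cfg.planted_changes) + _cluster_changes(cfg, layout)

    n_probes = cfg.n_genes * cfg.probes_per_gene
    s = cfg.intensity_scale
    beta_max = (s - 100.0) / s

    # baseline beta per probe from the mixture
    weights = np.array([c[0] for c in cfg.baseline_beta_distribution])
    comp = rng.choice(len(weights), size=n_probes, p=weights)
    base = np.empty(n_probes)
    for i, (_, a, b) in enumerate(cfg.baseline_beta_distribution):
        m = comp == i
        base[m] = rng.beta(a, b, size=int(m.sum()))
    # the intensity model caps representable beta at (s-100)/s
    base = np.clip(base, 0.0, beta_max)

    # planted genes get baselines redrawn with room for the shift
    gene_of_probe = np.repeat(np.arange(cfg.n_genes), cfg.probes_per_gene)
    shift = np.zeros((n_probes, len(cfg.groups)))
    gidx = {g: i for i, g in enumerate(cfg.groups)}
    for pc in all_changes:
        if pc.group_a not in gidx or pc.group_b not in gidx:
            raise ConfigError(f"unknown group in planted change: {pc}")
        sd = pc.signed_delta()
        pm = np.isin(gene_of_probe, pc.genes)
        # planted genes start at a distribution extreme and shift toward the
        # intermediate range, emulating partial-population methylation change
        if pc.direction == "gain":
            hi = min(0.15, beta_max - pc.delta - 0.02)
            base[pm] = rng.uniform(min(0.05, hi / 2), hi, size=int(pm.sum()))
        else:
            lo = max(0.85, pc.delta + 0.07)
            base[pm] = rng.uniform(lo, max(0.93, lo + 0.02),
                                   size=int(pm.sum()))
        shift[pm, gidx[pc.group_b]] += sd

    target = base[:, None] + shift          # (probes, groups) intended betas
    if target.min() < 0 or target.max() > beta_max:
        raise ConfigError(
            "planted deltas push intended beta outside "
            f"[0, {beta_max:.4f}]; reduce delta or rearrange planted sets"
        )

    samples = [f"G{g}_r{r+1}" for g in cfg.groups for r in range(cfg.n_replicates)]
    group_of_sample = np.repeat(np.arange(len(cfg.groups)), cfg.n_replicates)

    beta = target[:, group_of_sample]
    if cfg.sigma_beta > 0:
        beta = beta + rng.normal(0, cfg.sigma_beta, size=beta.shape)
    beta = np.clip(beta, 0.0, beta_max)

    M = beta * s
    U = s - 100.0 - M

    fail = rng.random((n_probes, len(samples))) < cfg.detection_p_failure_rate
    det = rng.uniform(0.0, 0.005, size=fail.shape)
    det[fail] = rng.uniform(0.05, 1.0, size=int(fail.sum()))

    probe_ids = np.array([
        f"cg{g:05d}_{p}" for g in range(cfg.n_genes) for p in range(cfg.probes_per_gene)
    ])
    ann = layout.set_index("gene_index")
    gene_names = ann.gene.to_numpy()[gene_of_probe]
    chroms = ann.chrom.to_numpy()[gene_of_probe]
    pos = ann.pos.to_numpy()[gene_of_probe] + np.tile(
        np.arange(cfg.probes_per_gene) * 500, cfg.n_genes
    )

    n_s = len(samples)
    probe_table = pd.DataFrame({
        "probe_id": np.repeat(probe_ids, n_s),
        "gene": np.repeat(gene_names, n_s),
        "chrom": np.repeat(chroms, n_s),
        "pos": np.repeat(pos, n_s),
        "sample_id": np.tile(samples, n_probes),
        "M": M.ravel(),
        "U": U.ravel(),
        "detection_p": det.ravel(),
    })

    cluster_genes = set()
    for pc in _cluster_changes(cfg, layout):
        cluster_genes.update(pc.genes)
    truth_rows = []
    for pc in all_changes:
        for g in pc.genes:
            truth_rows.append((
                ann.gene.loc[g], ann.chrom.loc[g], int(ann.pos.loc[g]),
                pc.group_a, pc.group_b, pc.delta, pc.direction,
                g in cluster_genes,
            ))
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene", "chrom", "pos", "group_a", "group_b",
                 "delta", "direction", "clustered"],
    )
    return probe_table, truth


def design_for(cfg: MethylationSimConfig) -> dict[str, str]:
    """sample_id -> group label map matching :func:`gen_methylation_dataset`."""
    return {
        f"G{g}_r{r+1}": str(g)
        for g in cfg.groups for r in range(cfg.n_replicates)
    }


# --------------------------------------------------------------------------
# MeDIP tags
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TagSimConfig:
    n_tags: int = 10_000
    groups: tuple[str, ...] = ("1", "2", "4")
    per_group_positive_rates: tuple[float, ...] = (0.49, 0.74, 0.20)
    triple_shared_fraction: float = 0.047
    # (sub-threshold mean/sd, supra-threshold exponential scale)
    log2_ratio_distributions: tuple[float, float, float] = (0.5, 0.8, 1.2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_tags < 1:
            raise ConfigError("n_tags must be >= 1")
        if len(self.groups) != 3 or len(self.per_group_positive_rates) != 3:
            raise ConfigError("exactly three groups with three positive rates")
        t = self.triple_shared_fraction
        if not 0 <= t <= 1:
            raise ConfigError("triple_shared_fraction must be in [0, 1]")
        for p in self.per_group_positive_rates:
            if not 0 <= p <= 1:
                raise ConfigError("positive rates must be in [0, 1]")
            if t < 1 and (p - t) / (1 - t) < 0:
                raise ConfigError(
                    f"positive rate {p} below triple_shared_fraction {t} "
                    "implies a negative section probability"
                )
            if t == 1 and p < 1:
                raise ConfigError("triple_shared_fraction=1 requires all rates 1")


def default_tag_config(seed: int = 0) -> TagSimConfig:
    """Marginal rates proportional to the three-group tag totals of the study
    design (unstimulated : cytokine : transduced roughly 49:74:20 per 100)."""
    return TagSimConfig(seed=seed)


def tag_section_probabilities(cfg: TagSimConfig) -> dict[str, float]:
    """Expected probability of each of the 8 disjoint membership patterns.

    Keys are 3-character strings of 0/1 flags in group order ("111" = shared
    by all three, "000" = in none).
    """
    cfg.validate()
    t = cfg.triple_shared_fraction
    if t == 1.0:
        q = [1.0, 1.0, 1.0]
    else:
        q = [(p - t) / (1 - t) for p in cfg.per_group_positive_rates]
    out = {}
    for a in (0, 1):
        for b in (0, 1):
            for c in (0, 1):
                pr = (1 - t)
                for flag, qq in zip((a, b, c), q):
                    pr *= qq if flag else (1 - qq)
                if (a, b, c) == (1, 1, 1):
                    pr += t
                out[f"{a}{b}{c}"] = pr
    return out


def gen_medip_tags(cfg: TagSimConfig):
    """Simulate a per-group log2-ratio tag table plus section truth.

    A tag is "positive" in a group when its log2 precipitated/input ratio
    exceeds 2; positive ratios are drawn strictly above the threshold and
    negative ratios strictly below it, so thresholding recovers the planted
    membership exactly.

    Returns
    -------
    tag_table : DataFrame
        Long format: tag_id, chrom, start, end, group, log2_ratio.
    truth : DataFrame
        tag_id, section (e.g. "110" in group order), plus one boolean
        membership column per group.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.triple_shared_fraction
    q = np.array([1.0, 1.0, 1.0]) if t == 1.0 else np.array(
        [(p - t) / (1 - t) for p in cfg.per_group_positive_rates]
    )

    forced = rng.random(cfg.n_tags) < t
    member = rng.random((cfg.n_tags, 3)) < q[None, :]
    member[forced, :] = True

    mu, sd, scale = cfg.log2_ratio_distributions
    neg = np.minimum(rng.normal(mu, sd, size=(cfg.n_tags, 3)), 1.95)
    pos = 2.0 + 0.05 + rng.exponential(scale, size=(cfg.n_tags, 3))
    ratio = np.where(member, pos, neg)

    tag_ids = np.array([f"TAG{i:06d}" for i in range(cfg.n_tags)])
    chroms = rng.choice(AUTOSOMES, size=cfg.n_tags)
    start = rng.integers(1, 200_000_000, size=cfg.n_tags)
    end = start + 999

    tag_table = pd.DataFrame({
        "tag_id": np.repeat(tag_ids, 3),
        "chrom": np.repeat(chroms, 3),
        "start": np.repeat(start, 3),
        "end": np.repeat(end, 3),
        "group": np.tile(np.array(cfg.groups), cfg.n_tags),
        "log2_ratio": ratio.ravel(),
    })

    section = np.array(["".join("1" if f else "0" for f in row) for row in member])
    truth = pd.DataFrame({"tag_id": tag_ids, "section": section})
    for j, g in enumerate(cfg.groups):
        truth[f"in_{g}"] = member[:, j]
    return tag_table, truth


# --------------------------------------------------------------------------
# serialization helpers
# --------------------------------------------------------------------------


def write_field(dapi, marker, truth, outdir, prefix="field"):
    """Write one field as two 8-bit TIFFs plus a 16-bit label TIFF."""
    import tifffile
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / f"{prefix}_dapi.tif", dapi)
    tifffile.imwrite(outdir / f"{prefix}_marker.tif", marker)
    tifffile.imwrite(outdir / f"{prefix}_truth.tif", truth)


def config_from_dict(kind: str, d: dict):
    """Rebuild a config dataclass from a plain JSON dict (CLI entry point)."""
    cls = {
        "images": ImageFieldConfig,
        "infinium": MethylationSimConfig,
        "medip": TagSimConfig,
    }[kind]
    d = dict(d)
    if cls is MethylationSimConfig:
        d["planted_changes"] = tuple(
            PlantedChange(tuple(p["genes"]), p["group_a"], p["group_b"],
                          p["delta"], p["direction"])
            for p in d.get("planted_changes", ())
        )
        d["clustered_regions"] = tuple(
            ClusteredRegion(c["chrom"], c["start_index"], c["length"],
                            tuple(c["changed"]), c["group_a"], c["group_b"],
                            c["delta"], c["direction"])
            for c in d.get("clustered_regions", ())
        )
    for f in dataclasses.fields(cls):
        if f.name in d and isinstance(d[f.name], list):
            d[f.name] = tuple(d[f.name])
    return cls(**d)
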