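"""Beta-value methylation analysis for a 27k-style CpG array.

The methylation score of a probe is the beta value

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100)

where M and U are the fluorescence intensities of the methylated and
unmethylated allele assays and the +100 offset stabilizes low-intensity
probes; beta ranges from 0 (unmethylated) to just under 1 (fully
methylated).

The module covers the downstream chain: three-step intensity normalization
(color-bias correction, background subtraction, quantile normalization),
probe filtering (detection p-value in every sample, allosome exclusion),
differential calling at an absolute median-beta difference >= 0.20,
unsupervised hierarchical clustering of samples on the called probes, and
per-group beta density profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "compute_beta",
    "normalize_intensities",
    "quantile_normalize",
    "BetaMatrix",
    "beta_matrix_from_probe_table",
    "filter_probes",
    "call_differential",
    "DifferentialCallSet",
    "cluster_samples",
    "ClusterResult",
    "beta_density_profile",
]

BETA_OFFSET = 100.0


def compute_beta(M, U):
    """Beta value(s) from methylated/unmethylated intensities.

    Negative intensities (background over-subtraction) clamp to 0; the
    result is 0 when M <= 0 and always strictly below 1.  Accepts scalars
    or arrays (broadcasting).
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.isfinite(M).all() and np.isfinite(U).all()):
        raise ValueError("intensities must be finite")
    Mc = np.maximum(M, 0.0)
    Uc = np.maximum(U, 0.0)
    b = Mc / (Mc + Uc + BETA_OFFSET)
    return float(b) if b.ndim == 0 else b


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns (samples).

    Every column is mapped onto the mean of the column-wise sorted values;
    ties within a column receive the mean of the reference values of their
    rank range.
    """
    ranks = df.rank(method="average")
    reference = np.sort(df.to_numpy(), axis=0).mean(axis=1)
    # interpolate the reference at (possibly fractional, tied) ranks
    grid = np.arange(1, len(df) + 1, dtype=float)
    out = {
        c: np.interp(ranks[c].to_numpy(), grid, reference) for c in df.columns
    }
    return pd.DataFrame(out, index=df.index)


def normalize_intensities(M: pd.DataFrame, U: pd.DataFrame):
    """Three-step normalization of raw channel intensities.

    1. color-bias correction: within each sample, each channel is scaled so
       its median equals the geometric mean of the two channel medians;
    2. background correction: within each sample and channel, the 5th
       percentile is subtracted and values clamp at 0;
    3. quantile normalization across samples, separately per channel.

    ``M`` and ``U`` are probes x samples frames with identical shape.
    With a single sample the quantile step is skipped with a warning.
    """
    if M.shape != U.shape or list(M.columns) != list(U.columns):
        raise ValueError("M and U frames must be aligned")
    Mn = M.astype(float).copy()
    Un = U.astype(float).copy()
    for s in Mn.columns:
        mM = Mn[s].median()
        mU = Un[s].median()
        if mM > 0 and mU > 0:
            g = np.sqrt(mM * mU)
            Mn[s] *= g / mM
            Un[s] *= g / mU
    for df in (Mn, Un):
        for s in df.columns:
            bg = np.percentile(df[s], 5)
            df[s] = np.maximum(df[s] - bg, 0.0)
    if Mn.shape[1] < 2:
        warnings.warn("single sample: quantile normalization skipped")
        return Mn, Un
    return quantile_normalize(Mn), quantile_normalize(Un)


@dataclass
class BetaMatrix:
    """Probes x samples beta values plus annotation and group design."""

    betas: pd.DataFrame                      # index probe_id, columns sample_id
    annotation: pd.DataFrame                 # index probe_id: gene, chrom, pos
    design: dict                             # sample_id -> group label
    detection_p: pd.DataFrame | None = None  # aligned with betas
    normalized: bool = False
    filtered: bool = False

    def __post_init__(self):
        if not self.annotation.index.equals(self.betas.index):
            self.annotation = self.annotation.loc[self.betas.index]
        missing = [s for s in self.betas.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        vals = self.betas.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("beta matrix contains missing values")
        if vals.min() < 0 or vals.max() >= 1:
            raise ValueError("beta values must lie in [0, 1)")

    def samples_of(self, group) -> list:
        return [s for s in self.betas.columns if self.design[s] == group]

    @property
    def groups(self):
        return sorted(set(self.design[s] for s in self.betas.columns))


def beta_matrix_from_probe_table(
    probe_table: pd.DataFrame, design: dict, normalize: bool = True
) -> BetaMatrix:
    """Pivot a long probe table into a BetaMatrix, optionally normalizing
    the raw intensities first."""
    M = probe_table.pivot(index="probe_id", columns="sample_id", values="M")
    U = probe_table.pivot(index="probe_id", columns="sample_id", values="U")
    det = probe_table.pivot(
        index="probe_id", columns="sample_id", values="detection_p"
    )
    if normalize:
        M, U = normalize_intensities(M, U)
    betas = pd.DataFrame(
        compute_beta(M.to_numpy(), U.to_numpy()),
        index=M.index, columns=M.columns,
    )
    ann = (
        probe_table[["probe_id", "gene", "chrom", "pos"]]
        .drop_duplicates("probe_id")
        .set_index("probe_id")
        .loc[betas.index]
    )
    return BetaMatrix(
        betas=betas, annotation=ann, design=dict(design),
        detection_p=det, normalized=normalize,
    )


def filter_probes(bm: BetaMatrix, alpha: float = 0.01) -> BetaMatrix:
    """Retain probes detected in every sample and located on autosomes.

    A probe is kept iff its detection p-value is <= ``alpha`` in *all*
    samples (a score missing for any array discards the probe) and its
    chromosome is not X or Y (sex-specific methylation confound).
    """
    if bm.detection_p is None:
        raise ValueError("detection p-values are required for filtering")
    det_ok = (bm.detection_p.loc[bm.betas.index] <= alpha).all(axis=1)
    auto_ok = ~bm.annotation.chrom.isin(("chrX", "chrY"))
    keep = det_ok & auto_ok
    if not keep.any():
        raise ValueError(
            "all probes removed: "
            f"{int((~det_ok).sum())} failed detection in >=1 sample, "
            f"{int((~auto_ok).sum())} on allosomes"
        )
    return BetaMatrix(
        betas=bm.betas.loc[keep],
        annotation=bm.annotation.loc[keep],
        design=bm.design,
        detection_p=bm.detection_p.loc[keep],
        normalized=bm.normalized,
        filtered=True,
    )


@dataclass
class DifferentialCallSet:
    """Genes whose median beta changed by >= ``threshold`` between groups.

    ``delta`` is median(group_b) - median(group_a) of the strongest probe;
    gained = methylation increased in group_b, lost = decreased.  A gene
    with probes called in both directions is assigned to its largest
    |delta| and flagged.
    """

    group_a: str
    group_b: str
    threshold: float
    gained: set
    lost: set
    table: pd.DataFrame        # gene, chrom, pos, delta, direction, flagged
    probe_deltas: pd.Series    # per-probe median-beta difference

    @property
    def called(self) -> set:
        return self.gained | self.lost


def call_differential(
    bm: BetaMatrix, group_a, group_b, delta: float = 0.20
) -> DifferentialCallSet:
    """Call differentially methylated genes between two groups.

    Per probe, the difference of within-group median betas is computed; a
    probe is called when |difference| >= ``delta`` (inclusive).  A gene is
    called in a direction if any of its probes is; conflicting directions
    resolve to the largest |difference| and are flagged.
    """
    for g in (group_a, group_b):
        if g not in bm.groups:
            raise ValueError(f"unknown group label {g!r}")
    sa = bm.samples_of(group_a)
    sb = bm.samples_of(group_b)
    if not sa or not sb:
        raise ValueError("each group needs at least one sample")
    med_a = bm.betas[sa].median(axis=1)
    med_b = bm.betas[sb].median(axis=1)
    d = med_b - med_a
    # inclusive threshold, robust to float representation of the medians
    called = d.abs() >= delta - 1e-12

    rows = []
    gained, lost = set(), set()
    ann = bm.annotation
    for gene, idx in ann.groupby("gene").groups.items():
        dg = d.loc[idx][called.loc[idx]]
        if dg.empty:
            continue
        best = dg.loc[dg.abs().idxmax()]
        flagged = (dg > 0).any() and (dg < 0).any()
        direction = "gain" if best > 0 else "loss"
        (gained if best > 0 else lost).add(gene)
        first = ann.loc[idx[0]]
        rows.append((gene, first.chrom, int(first.pos), float(best),
                     direction, bool(flagged)))
    table = pd.DataFrame(
        rows, columns=["gene", "chrom", "pos", "delta", "direction", "flagged"]
    ).sort_values(["chrom", "pos", "gene"]).reset_index(drop=True)
    return DifferentialCallSet(
        group_a=str(group_a), group_b=str(group_b), threshold=delta,
        gained=gained, lost=lost, table=table, probe_deltas=d,
    )


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaves: list                        # sample ids in dendrogram order
    newick: str
    cophenetic: pd.DataFrame            # sample x sample cophenetic distances


def _to_newick(node, names) -> str:
    if node.is_leaf():
        return names[node.id]
    left = _to_newick(node.get_left(), names)
    right = _to_newick(node.get_right(), names)
    bl_l = node.dist - node.get_left().dist
    bl_r = node.dist - node.get_right().dist
    return f"({left}:{bl_l:.6g},{right}:{bl_r:.6g})"


def cluster_samples(bm: BetaMatrix, probe_ids=None) -> ClusterResult:
    """Unsupervised hierarchical clustering of samples.

    Euclidean distance on the (called-probe) beta vectors, average linkage,
    deterministic leaf order (scipy's tightest-cluster-first ordering).
    ``probe_ids`` restricts the matrix, typically to differentially called
    probes.
    """
    betas = bm.betas if probe_ids is None else bm.betas.loc[list(probe_ids)]
    if betas.empty:
        raise ValueError("no probes to cluster on")
    if betas.shape[1] < 2:
        raise ValueError("clustering needs at least two samples")
    X = betas.to_numpy().T
    dist = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(dist, method="average")
    names = list(betas.columns)
    leaves = [names[i] for i in hierarchy.leaves_list(Z)]
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, names) + ";"
    coph = squareform(hierarchy.cophenet(Z, dist)[1])
    return ClusterResult(
        linkage=Z, leaves=leaves, newick=newick,
        cophenetic=pd.DataFrame(coph, index=names, columns=names),
    )


def beta_density_profile(bm: BetaMatrix, group, bins: int = 50):
    """Density of per-probe median betas of one group over [0, 1].

    The group's replicates are reduced to a per-probe median first (one
    value per locus), then binned into ``bins`` equal-width bins on [0, 1]
    as a normalized density (integral 1).

    Returns (bin_edges, density).
    """
    samples = bm.samples_of(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    med = bm.betas[samples].median(axis=1).to_numpy()
    density, edges = np.histogram(med, bins=bins, range=(0.0, 1.0), density=True)
    return edges, density
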