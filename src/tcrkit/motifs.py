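"""3-mer motif features: extraction, filtering, normalization, embedding.

A repertoire is summarized as the abundance distribution of its CDR3
3-mers, a vector over at most 20^3 = 8000 dimensions.  Samples x motifs
count matrices are then denoised in stages:

``raw`` -> ``sample_filtered`` (drop samples in the extreme total-motif
quantiles) -> ``prevalence_filtered`` (keep motifs present in more than
half of a disease group) -> ``mwu_filtered`` (keep motifs whose
distribution differs between disease and healthy samples by a two-sided
Mann-Whitney U test at alpha) -> ``normalized`` (per-motif z-scores).

The normalized matrix is embedded into two dimensions with a diffusion-map
/ potential-distance procedure (k-NN Gaussian affinities, a row-stochastic
diffusion operator raised to t steps, log-potential distances, classical
metric scaling); a plug-in seam accepts any callable with the same
signature, e.g. an external PHATE implementation.  New samples are placed
by Nystrom-style kernel interpolation over the nearest reference samples.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform
from scipy.stats import norm, rankdata

from .errors import EmptyInputError, StageError
from .model import AA_ALPHABET, Repertoire

logger = logging.getLogger(__name__)

STAGES = ("raw", "sample_filtered", "prevalence_filtered", "mwu_filtered", "normalized")


def motif_universe(k: int = 3) -> list[str]:
    """All k-mers over the 20 standard amino acids (8000 strings at k=3)."""
    return ["".join(t) for t in itertools.product(AA_ALPHABET, repeat=k)]


def count_kmers(rep: Repertoire, k: int = 3, weighted: bool = False) -> Counter:
    """Sliding-window k-mer counts over the unique CDR3s of a repertoire.

    A sequence of length L contributes L-k+1 windows; ``weighted=True``
    multiplies each sequence's windows by its clone count.  Sequences
    shorter than k contribute nothing (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Counter = Counter()
    for c in rep.clonotypes:
        s = c.cdr3_aa
        if len(s) < k:
            logger.warning("sequence %s shorter than k=%d; skipped", s, k)
            continue
        w = c.count if weighted else 1
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += w
    return counts


@dataclass
class MotifMatrix:
    """Samples x motifs matrix with group labels and a pipeline stage tag.

    ``values`` rows are sample ids, columns are k-mer strings; raw entries
    are non-negative integer counts.  After :func:`zscore_normalize` the
    per-column means and population SDs used are retained for projecting
    new samples onto the same scale.
    """

    values: pd.DataFrame
    labels: dict[str, str]
    stage: str = "raw"
    k: int = 3
    column_means: pd.Series | None = None
    column_stds: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def motifs(self) -> list[str]:
        return list(self.values.columns)

    def group_rows(self, group: str) -> pd.DataFrame:
        ids = [s for s in self.sample_ids if self.labels.get(s) == group]
        return self.values.loc[ids]

    def to_tsv(self, path, sidecar: str | Path | None = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")
        if sidecar is not None:
            meta = {
                "stage": self.stage,
                "k": self.k,
                "labels": {s: self.labels.get(s, "") for s in self.sample_ids},
                "column_means": None
                if self.column_means is None
                else self.column_means.to_dict(),
                "column_stds": None
                if self.column_stds is None
                else self.column_stds.to_dict(),
            }
            with open(sidecar, "w", encoding="utf-8") as fh:
                json.dump(meta, fh)


def read_motif_matrix(path: str | Path, sidecar: str | Path) -> MotifMatrix:
    values = pd.read_csv(path, sep="\t", index_col="sample_id")
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    return MotifMatrix(
        values=values,
        labels=dict(meta["labels"]),
        stage=meta["stage"],
        k=int(meta.get("k", 3)),
        column_means=None
        if meta["column_means"] is None
        else pd.Series(meta["column_means"]),
        column_stds=None
        if meta["column_stds"] is None
        else pd.Series(meta["column_stds"]),
    )


def build_motif_matrix(
    samples: Sequence[Repertoire],
    labels: Mapping[str, str] | None = None,
    k: int = 3,
    weighted: bool = False,
) -> MotifMatrix:
    """Stack per-sample k-mer counts into a raw matrix.

    Columns are the union of observed motifs in lexicographic order; a
    motif absent from a sample is a zero count.
    """
    if not samples:
        raise EmptyInputError("no samples")
    ids = [r.sample_id for r in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id among samples")
    counters = {r.sample_id: count_kmers(r, k=k, weighted=weighted) for r in samples}
    motifs = sorted(set().union(*[set(c) for c in counters.values()]))
    values = pd.DataFrame(
        [[counters[s].get(m, 0) for m in motifs] for s in ids],
        index=ids,
        columns=motifs,
        dtype=np.int64,
    )
    labels = dict(labels or {})
    return MotifMatrix(values=values, labels=labels, stage="raw", k=k)


def _require_stage(m: MotifMatrix, allowed: tuple[str, ...]) -> None:
    if m.stage not in allowed:
        raise StageError(f"operation requires stage in {allowed}, got {m.stage!r}")


def filter_samples(
    m: MotifMatrix, lower_q: float = 0.2, upper_q: float = 0.2
) -> MotifMatrix:
    """Drop samples in the extreme tails of total motif count.

    Rank-based: the ``ceil(n * q)`` lowest-total and highest-total samples
    are removed (ties broken by sample id), so any non-empty tail removes
    at least one sample when ``q > 0``.
    """
    _require_stage(m, ("raw",))
    totals = m.values.sum(axis=1)
    order = sorted(m.sample_ids, key=lambda s: (totals[s], s))
    n = len(order)
    k_lo = math.ceil(n * lower_q) if lower_q > 0 else 0
    k_hi = math.ceil(n * upper_q) if upper_q > 0 else 0
    keep = order[k_lo : n - k_hi] if n - k_hi > k_lo else []
    if not keep:
        raise EmptyInputError("sample filter removed every sample")
    keep_in_order = [s for s in m.sample_ids if s in set(keep)]
    return MotifMatrix(
        values=m.values.loc[keep_in_order].copy(),
        labels=dict(m.labels),
        stage="sample_filtered",
        k=m.k,
    )


def filter_prevalence(
    m: MotifMatrix, group: str, min_frac: float = 0.5
) -> MotifMatrix:
    """Keep motifs present (count > 0) in strictly more than ``min_frac`` of
    the ``group`` samples; a disease-specific motif should recur across the
    majority of that disease's samples."""
    _require_stage(m, ("raw", "sample_filtered"))
    rows = m.group_rows(group)
    if rows.empty:
        raise KeyError(f"no samples labelled {group!r}")
    prevalence = (rows > 0).mean(axis=0)
    keep = [mo for mo in m.motifs if prevalence[mo] > min_frac]
    return MotifMatrix(
        values=m.values[keep].copy(),
        labels=dict(m.labels),
        stage="prevalence_filtered",
        k=m.k,
    )


_EXACT_MAX_PRODUCT = 400
_EXACT_MAX_COMBINATIONS = 20_000


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs in which x exceeds y (ties
    count one half).  Small samples (``n*m <= 400`` and a tractable number
    of group assignments) get an exact permutation p value computed by
    enumeration over pooled-rank subsets, which handles ties exactly;
    larger samples use the normal approximation with tie-corrected variance
    and a continuity correction.  Identical pooled values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n == 0 or m == 0:
        raise EmptyInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)

    _, tie_counts = np.unique(pooled, return_counts=True)
    if tie_counts.size == 1:  # every value identical
        return u, 1.0

    try:
        n_comb = math.comb(n + m, n)
    except OverflowError:
        n_comb = _EXACT_MAX_COMBINATIONS + 1
    if n * m <= _EXACT_MAX_PRODUCT and n_comb <= _EXACT_MAX_COMBINATIONS:
        offset = n * (n + 1) / 2.0
        idx = np.array(list(itertools.combinations(range(n + m), n)), dtype=np.intp)
        null = ranks[idx].sum(axis=1) - offset
        # two-sided: as-or-more extreme on either side of the mean nm/2
        eps = 1e-9
        d = abs(u - n * m / 2.0)
        p = float((np.abs(null - n * m / 2.0) >= d - eps).mean())
        return u, min(1.0, p)

    mean = n * m / 2.0
    nm_total = n + m
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (nm_total * (nm_total - 1))
    var = n * m / 12.0 * ((nm_total + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    diff = u - mean
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var)
    return u, float(min(1.0, 2.0 * norm.sf(abs(z))))


def filter_mwu(
    disease: MotifMatrix,
    healthy: MotifMatrix,
    alpha: float = 0.05,
    use_frequencies: bool = False,
) -> MotifMatrix:
    """Keep motifs whose per-sample distributions differ between the
    disease and healthy matrices (two-sided MWU, ``p <= alpha``).

    Motifs absent from the healthy matrix are compared against an all-zero
    healthy vector.  ``use_frequencies`` rescales each sample's counts by
    its total window count before testing.
    """
    _require_stage(disease, ("prevalence_filtered",))
    _require_stage(healthy, ("raw", "sample_filtered", "prevalence_filtered"))
    if healthy.values.shape[0] == 0 or disease.values.shape[0] == 0:
        raise EmptyInputError("both matrices need at least one sample")

    dvals = disease.values.astype(float)
    hvals = healthy.values.astype(float)
    if use_frequencies:
        dvals = dvals.div(dvals.sum(axis=1).replace(0, 1), axis=0)
        hvals = hvals.div(hvals.sum(axis=1).replace(0, 1), axis=0)
    zeros = np.zeros(hvals.shape[0])
    keep = []
    for motif in disease.motifs:
        x = dvals[motif].to_numpy()
        y = hvals[motif].to_numpy() if motif in hvals.columns else zeros
        _, p = mann_whitney_u(x, y)
        if p <= alpha:
            keep.append(motif)
    return MotifMatrix(
        values=disease.values[keep].copy(),
        labels=dict(disease.labels),
        stage="mwu_filtered",
        k=disease.k,
    )


def zscore_normalize(m: MotifMatrix) -> MotifMatrix:
    """Per-motif z-scores across samples using the population SD.

    Zero-variance columns become all zeros.  The means and SDs are stored
    on the result so held-out samples can be projected onto the same scale.
    """
    _require_stage(m, STAGES[:-1])
    vals = m.values.astype(float)
    means = vals.mean(axis=0)
    stds = vals.std(axis=0, ddof=0)
    safe = stds.replace(0, 1.0)
    z = (vals - means) / safe
    z.loc[:, stds == 0] = 0.0
    return MotifMatrix(
        values=z,
        labels=dict(m.labels),
        stage="normalized",
        k=m.k,
        column_means=means,
        column_stds=stds,
    )


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingModel:
    """A fitted 2-D reference embedding plus everything needed to project
    new samples: the normalized reference features (with their column means
    and SDs) and the fitted coordinates."""

    reference_coordinates: pd.DataFrame
    reference_features: MotifMatrix
    backend_tag: str = "diffusion"
    fit_parameters: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference_coordinates.to_csv(
            outdir / "coordinates.tsv", sep="\t", index_label="sample_id"
        )
        self.reference_features.to_tsv(
            outdir / "features.tsv", sidecar=outdir / "features.json"
        )
        with open(outdir / "model.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"backend_tag": self.backend_tag, "fit_parameters": self.fit_parameters},
                fh,
            )

    @classmethod
    def load(cls, outdir: str | Path) -> "EmbeddingModel":
        outdir = Path(outdir)
        coords = pd.read_csv(outdir / "coordinates.tsv", sep="\t", index_col="sample_id")
        feats = read_motif_matrix(outdir / "features.tsv", outdir / "features.json")
        with open(outdir / "model.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            reference_coordinates=coords,
            reference_features=feats,
            backend_tag=meta["backend_tag"],
            fit_parameters=meta["fit_parameters"],
        )


def _fix_signs(coords: np.ndarray) -> np.ndarray:
    """Make eigenvector signs deterministic: largest-|value| entry positive."""
    for j in range(coords.shape[1]):
        col = coords[:, j]
        i = np.argmax(np.abs(col))
        if col[i] < 0:
            coords[:, j] = -col
    return coords


def _diffusion_backend(
    X: np.ndarray, n_components: int, knn: int, t: int, seed: int
) -> np.ndarray:
    """Diffusion-map / potential-distance embedding.

    Gaussian affinities with adaptive per-point bandwidth (distance to the
    ``knn``-th neighbour), symmetrized, row-normalized to a diffusion
    operator, raised to ``t`` steps; minus-log potentials are compared by
    Euclidean distance and reduced with classical metric scaling.  The
    procedure is deterministic; ``seed`` is part of the backend signature
    for stochastic plug-ins.
    """
    n = X.shape[0]
    D = squareform(pdist(X))
    k = min(knn, n - 1)
    knn_dist = np.sort(D, axis=1)[:, k]
    knn_dist[knn_dist <= 0] = np.max(D) * 1e-3 + 1e-12
    A = np.exp(-((D / knn_dist[:, None]) ** 2))
    A = 0.5 * (A + A.T)
    P = A / A.sum(axis=1, keepdims=True)
    Pt = np.linalg.matrix_power(P, t)
    potential = -np.log(Pt + 1e-12)
    PD = squareform(pdist(potential))
    # classical MDS
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (PD**2) @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_components]
    coords = v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))
    return _fix_signs(coords)


EmbeddingBackend = Callable[[np.ndarray, int, int, int, int], np.ndarray]


def fit_embedding(
    m: MotifMatrix,
    n_components: int = 2,
    backend: str | EmbeddingBackend = "diffusion",
    seed: int = 0,
    knn: int = 5,
    t: int = 3,
) -> EmbeddingModel:
    """Fit the low-dimensional reference embedding on a normalized matrix.

    ``backend`` may be the built-in ``"diffusion"`` procedure or any
    callable ``(X, n_components, knn, t, seed) -> coords``; this is the
    seam for an external PHATE implementation.
    """
    _require_stage(m, ("normalized",))
    n = m.values.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} samples, got {n}")
    X = m.values.to_numpy(dtype=float)
    if callable(backend):
        coords = backend(X, n_components, knn, t, seed)
        tag = getattr(backend, "__name__", "custom")
    elif backend == "diffusion":
        coords = _diffusion_backend(X, n_components, knn, t, seed)
        tag = "diffusion"
    else:
        raise ValueError(f"unknown backend {backend!r}")
    frame = pd.DataFrame(
        coords,
        index=m.sample_ids,
        columns=[f"dim{i + 1}" for i in range(n_components)],
    )
    return EmbeddingModel(
        reference_coordinates=frame,
        reference_features=m,
        backend_tag=tag,
        fit_parameters={"n_components": n_components, "knn": knn, "t": t, "seed": seed},
    )


def embed_new(
    model: EmbeddingModel,
    sample: Mapping[str, float] | pd.Series | Counter,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Project one new sample's raw motif counts into the fitted space.

    The vector is aligned to the model's motif columns (missing motifs are
    zero), z-scored with the stored reference means/SDs, and placed by a
    Nystrom-style Gaussian-kernel average over the ``n_neighbors`` nearest
    reference samples.  An all-zero aligned vector triggers a warning and
    returns the kernel-free reference centroid.
    """
    feats = model.reference_features
    aligned = pd.Series(dict(sample), dtype=float).reindex(feats.motifs).fillna(0.0)
    coords = model.reference_coordinates.to_numpy(dtype=float)
    if (aligned == 0).all():
        logger.warning("all-zero motif vector; returning reference centroid")
        return coords.mean(axis=0)
    stds = feats.column_stds.replace(0, 1.0)
    z = ((aligned - feats.column_means) / stds).to_numpy(dtype=float)
    z[feats.column_stds.to_numpy() == 0] = 0.0

    X = feats.values.to_numpy(dtype=float)
    d = cdist(z[None, :], X)[0]
    k = min(n_neighbors, d.size)
    nearest = np.argsort(d, kind="stable")[:k]
    dn = d[nearest]
    sigma = 0.5 * np.median(dn[dn > 0]) if np.any(dn > 0) else 1.0
    w = np.exp(-((dn / sigma) ** 2))
    if w.sum() <= 0 or not np.isfinite(w.sum()):
        w = np.ones_like(dn)
    return (coords[nearest] * w[:, None]).sum(axis=0) / w.sum()


def discriminative_pipeline(
    samples: Sequence[Repertoire],
    labels: Mapping[str, str],
    healthy_label: str | None = "healthy",
    sample_filter: bool = True,
    lower_q: float = 0.2,
    upper_q: float = 0.2,
    min_frac: float = 0.5,
    alpha: float = 0.05,
    k: int = 3,
    weighted: bool = False,
) -> MotifMatrix:
    """Run the full motif-denoising pipeline and return the normalized
    disease matrix restricted to group-discriminative motifs.

    Disease groups are all labels other than ``healthy_label``.  Each
    disease group contributes the motifs that survive its prevalence filter
    and the MWU filter against the healthy samples; when no healthy samples
    exist the remaining groups serve as each disease's background.  The
    union of surviving motifs is z-score normalized over the disease
    samples.
    """
    matrix = build_motif_matrix(samples, labels, k=k, weighted=weighted)
    if sample_filter:
        matrix = filter_samples(matrix, lower_q, upper_q)
    else:
        matrix = MotifMatrix(
            values=matrix.values, labels=dict(labels), stage="sample_filtered", k=k
        )
    groups = sorted({labels[s] for s in matrix.sample_ids})
    disease_groups = [g for g in groups if g != healthy_label]
    if not disease_groups:
        raise EmptyInputError("no disease groups after filtering")
    have_healthy = healthy_label in groups

    kept: list[str] = []
    seen: set[str] = set()
    for g in disease_groups:
        prev = filter_prevalence(matrix, g, min_frac)
        disease_rows = [s for s in matrix.sample_ids if labels[s] == g]
        if have_healthy:
            bg_rows = [s for s in matrix.sample_ids if labels[s] == healthy_label]
        else:
            bg_rows = [s for s in matrix.sample_ids if labels[s] != g]
        dis = MotifMatrix(
            values=prev.values.loc[disease_rows],
            labels=dict(labels),
            stage="prevalence_filtered",
            k=k,
        )
        bg = MotifMatrix(
            values=matrix.values.loc[bg_rows],
            labels=dict(labels),
            stage="sample_filtered",
            k=k,
        )
        surv = filter_mwu(dis, bg, alpha=alpha)
        for mo in surv.motifs:
            if mo not in seen:
                seen.add(mo)
                kept.append(mo)
    disease_ids = [s for s in matrix.sample_ids if labels[s] != healthy_label]
    final = MotifMatrix(
        values=matrix.values.loc[disease_ids, sorted(kept)],
        labels=dict(labels),
        stage="mwu_filtered",
        k=k,
    )
    return zscore_normalize(final)
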