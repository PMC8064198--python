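"""Multi-class color quantization of H&E-like tiles.

The first stage of the sTIL algorithm: the intensity distribution of each
RGB channel is decomposed into a Gaussian mixture by EM; the pooled
component means (all channels, as scalars tagged with their channel) are
k-means-clustered into K groups; per-channel thresholds fall at midpoints
between consecutive cluster centers projected onto that channel, and each
pixel is assigned to the nearest class centroid in RGB space. The number
of classes K is chosen by maximizing the Dunn cluster-validity index over
a candidate range on a pixel subsample, ties broken toward the smaller K.
Finally each quantization class is annotated with a semantic tissue class
(nucleus / cytoplasm / stroma / other) by nearest stain prototype.

EM runs on the weighted histogram of the (8-bit) channel values, which is
exactly equivalent to running it on the raw sample but independent of
pixel order and much faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .types import CYTOPLASM, NUCLEUS, OTHER, STROMA, RGBTile, SemanticMap

DEFAULT_SEMANTIC_PROTOTYPES: dict[int, tuple[float, float, float]] = {
    NUCLEUS: (80.0, 60.0, 130.0),
    CYTOPLASM: (150.0, 120.0, 180.0),
    STROMA: (220.0, 160.0, 190.0),
    OTHER: (245.0, 245.0, 245.0),
}


class DegenerateModelError(RuntimeError):
    """EM could not produce a usable mixture (after bounded restarts)."""


class ThresholdError(ValueError):
    """Requested class count exceeds the distinct component means."""


@dataclass
class ChannelGMM:
    """A fitted univariate Gaussian mixture for one color channel.

    ``components`` is a list of (weight, mean, variance), sorted by mean.
    """

    channel: str
    components: list[tuple[float, float, float]]
    log_likelihood: float
    n_iterations: int
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        v = np.array([c[2] for c in self.components])
        if abs(w.sum() - 1.0) > 1e-9 or (w <= 0).any():
            raise ValueError("component weights must be positive and sum to 1")
        if (v <= 0).any():
            raise ValueError("component variances must be positive")

    @property
    def means(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])


def _em_weighted(
    x: np.ndarray,
    counts: np.ndarray,
    means: np.ndarray,
    variances: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_iter: int,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], int]:
    n = counts.sum()
    trace: list[float] = []
    prev = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # E step: responsibilities over the distinct values
        log_pdf = (
            -0.5 * np.log(2 * np.pi * variances)[None, :]
            - 0.5 * (x[:, None] - means[None, :]) ** 2 / variances[None, :]
        )
        log_w = np.log(weights)[None, :] + log_pdf
        m = log_w.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_w - m).sum(axis=1))
        loglik = float((counts * lse).sum())
        trace.append(loglik)
        resp = np.exp(log_w - lse[:, None]) * counts[:, None]
        # M step
        nk = resp.sum(axis=0)
        if (nk <= n * 1e-12).any() or not np.isfinite(loglik):
            raise DegenerateModelError("component collapsed during EM")
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, variance_floor)
        if loglik - prev < tol and it > 1:
            break
        prev = loglik
    return means, variances, weights, trace, it


def _weighted_kmeans_1d(x: np.ndarray, counts: np.ndarray, K: int) -> np.ndarray:
    """Exact count-weighted 1-D k-means of sorted distinct values; returns
    the K cluster means (used to initialize EM at the histogram modes)."""
    order = np.argsort(x)
    xs, ws = x[order], counts[order]
    n = len(xs)
    K = min(K, n)
    pw = np.concatenate([[0.0], np.cumsum(ws)])
    pwx = np.concatenate([[0.0], np.cumsum(ws * xs)])
    pwx2 = np.concatenate([[0.0], np.cumsum(ws * xs**2)])

    def cost(i: int, j: int) -> float:
        w, sx, sx2 = pw[j] - pw[i], pwx[j] - pwx[i], pwx2[j] - pwx2[i]
        return float(sx2 - sx * sx / w) if w > 0 else 0.0

    dp = np.full((K + 1, n + 1), np.inf)
    back = np.zeros((K + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            for i in range(k - 1, j):
                c = dp[k - 1, i] + cost(i, j)
                if c < dp[k, j] - 1e-12:
                    dp[k, j] = c
                    back[k, j] = i
    means = []
    j = n
    for k in range(K, 0, -1):
        i = back[k, j]
        means.append((pwx[j] - pwx[i]) / (pw[j] - pw[i]))
        j = i
    return np.array(means[::-1])


def fit_channel_gmm(
    values: np.ndarray,
    n_components: int = 4,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
    variance_floor: float = 1e-2,
    channel: str = "R",
    max_restarts: int = 5,
) -> ChannelGMM:
    """Fit a univariate GMM to an intensity sample by EM.

    Components are returned sorted by mean; the log-likelihood trace is
    non-decreasing. A collapsing component triggers a jittered restart, up
    to ``max_restarts`` times, after which :class:`DegenerateModelError`
    is raised.
    """
    values = np.asarray(values, dtype=float).ravel()
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if values.size < 10 * n_components:
        raise ValueError(f"need at least {10 * n_components} values for {n_components} components")
    x, counts = np.unique(values, return_counts=True)
    counts = counts.astype(float)
    rng = np.random.default_rng(seed)
    spread = max(float(x.max() - x.min()), 1.0)
    last_err: Optional[Exception] = None
    init_means = _weighted_kmeans_1d(x, counts, n_components)
    if len(init_means) < n_components:  # fewer distinct values than components
        init_means = np.concatenate(
            [init_means, np.full(n_components - len(init_means), init_means[-1])]
        )
    for attempt in range(max_restarts + 1):
        means0 = init_means.copy()
        if attempt > 0:
            means0 = means0 + rng.normal(0, spread / (2 * n_components), n_components)
        var0 = np.full(n_components, max((spread / (2 * n_components)) ** 2, variance_floor))
        w0 = np.full(n_components, 1.0 / n_components)
        try:
            means, variances, weights, trace, it = _em_weighted(
                x, counts, means0.astype(float), var0, w0, tol, max_iter, variance_floor
            )
        except DegenerateModelError as err:
            last_err = err
            continue
        order = np.argsort(means)
        comps = [(float(weights[k]), float(means[k]), float(variances[k])) for k in order]
        return ChannelGMM(
            channel=channel,
            components=comps,
            log_likelihood=trace[-1],
            n_iterations=it,
            loglik_trace=trace,
        )
    raise DegenerateModelError(f"EM failed after {max_restarts} restarts: {last_err}")


# ---------------------------------------------------------------------------
# threshold derivation


@dataclass
class QuantizationScheme:
    """K-class quantization derived from per-channel mixtures.

    ``thresholds`` maps channel id to its ordered (strictly increasing)
    threshold list; ``centroids`` is the (K, n_channels) array of class
    centers used for nearest-centroid pixel assignment, ordered by overall
    intensity; ``class_fractions`` is the mixture-weight estimate of each
    class's pixel fraction.
    """

    K: int
    channels: list[str]
    thresholds: dict[str, list[float]]
    centroids: np.ndarray
    class_fractions: np.ndarray
    cluster_members: list[list[tuple[str, float, float]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ch, th in self.thresholds.items():
            if any(b - a <= 0 for a, b in zip(th, th[1:])):
                raise ValueError(f"thresholds for channel {ch} must be strictly increasing")
        s = float(np.sum(self.class_fractions))
        if abs(s - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def _kmeans_1d(values: np.ndarray, K: int) -> list[np.ndarray]:
    """Optimal 1-D k-means (minimum within-cluster sum of squares) by
    dynamic programming over the sorted values; returns index groups."""
    order = np.argsort(values)
    xs = values[order]
    n = len(xs)
    pref = np.concatenate([[0.0], np.cumsum(xs)])
    pref2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def cost(i: int, j: int) -> float:  # xs[i:j]
        s, s2, m = pref[j] - pref[i], pref2[j] - pref2[i], j - i
        return float(s2 - s * s / m)

    dp = np.full((K + 1, n + 1), np.inf)
    back = np.zeros((K + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for k in range(1, K + 1):
        for j in range(k, n + 1):
            for i in range(k - 1, j):
                c = dp[k - 1, i] + cost(i, j)
                if c < dp[k, j] - 1e-12:
                    dp[k, j] = c
                    back[k, j] = i
    groups: list[np.ndarray] = []
    j = n
    for k in range(K, 0, -1):
        i = back[k, j]
        groups.append(order[i:j])
        j = i
    return groups[::-1]


def derive_thresholds(
    gmms: Sequence[ChannelGMM], K: int, seed: Optional[int] = None
) -> QuantizationScheme:
    """Cluster all pooled GMM component means into K classes.

    Component means from every channel are pooled as scalars (tagged with
    their channel) and partitioned by exact 1-D k-means. Per-channel
    thresholds are midpoints between consecutive distinct cluster centers
    projected onto that channel; the class centroid's coordinate in each
    channel is the weight-averaged mean of that cluster's components from
    the channel (falling back to the cluster's scalar center when the
    cluster holds no component of that channel). Deterministic; ``seed``
    is accepted for interface uniformity.
    """
    tagged = [
        (g.channel, w, m)
        for g in gmms
        for (w, m, _v) in g.components
    ]
    means = np.array([m for _c, _w, m in tagged])
    if len(np.unique(means)) < K:
        raise ThresholdError(
            f"K={K} exceeds the {len(np.unique(means))} distinct component means"
        )
    groups = _kmeans_1d(means, K)
    centers = np.array([means[g].mean() for g in groups])
    order = np.argsort(centers)
    groups = [groups[i] for i in order]
    centers = centers[order]

    channels = [g.channel for g in gmms]
    members = [[(tagged[i][0], tagged[i][1], tagged[i][2]) for i in g] for g in groups]
    centroids = np.empty((K, len(channels)))
    fractions = np.zeros(K)
    for k, mem in enumerate(members):
        fractions[k] = sum(w for _c, w, _m in mem)
        for j, ch in enumerate(channels):
            ws = [(w, m) for c, w, m in mem if c == ch]
            if ws:
                tot = sum(w for w, _ in ws)
                centroids[k, j] = sum(w * m for w, m in ws) / tot
            else:
                centroids[k, j] = centers[k]
    fractions = fractions / fractions.sum()

    thresholds: dict[str, list[float]] = {}
    for j, ch in enumerate(channels):
        proj = []
        for k, mem in enumerate(members):
            if any(c == ch for c, _w, _m in mem):
                proj.append(centroids[k, j])
        proj = sorted(set(proj))
        thresholds[ch] = [(a + b) / 2.0 for a, b in zip(proj, proj[1:])]

    return QuantizationScheme(
        K=K,
        channels=channels,
        thresholds=thresholds,
        centroids=centroids,
        class_fractions=fractions,
        cluster_members=members,
    )


# ---------------------------------------------------------------------------
# quantization and validity


def quantize(tile: RGBTile | np.ndarray, scheme: QuantizationScheme) -> np.ndarray:
    """Assign every pixel to its nearest class centroid in RGB space."""
    px = tile.pixels if isinstance(tile, RGBTile) else np.asarray(tile)
    flat = px.reshape(-1, px.shape[-1]).astype(float)
    d = cdist(flat, scheme.centroids, metric="sqeuclidean")
    return d.argmin(axis=1).reshape(px.shape[:-1])


def class_descriptors(
    tile: RGBTile | np.ndarray, labels: np.ndarray, K: int
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-class mean RGB and pixel fraction."""
    px = (tile.pixels if isinstance(tile, RGBTile) else np.asarray(tile)).reshape(-1, 3).astype(float)
    lab = labels.ravel()
    means = np.zeros((K, 3))
    fracs = np.zeros(K)
    for k in range(K):
        sel = lab == k
        fracs[k] = sel.mean()
        if sel.any():
            means[k] = px[sel].mean(axis=0)
    return means, fracs


def dunn_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Dunn cluster-validity index.

    Ratio of the minimum inter-cluster point distance to the maximum
    intra-cluster diameter; larger is better. All-singleton clusterings
    (zero diameter everywhere) return ``inf``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index requires at least 2 clusters")
    groups = [points[labels == u] for u in uniq]
    max_diam = 0.0
    for g in groups:
        if len(g) > 1:
            max_diam = max(max_diam, float(cdist(g, g).max()))
    min_sep = np.inf
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            min_sep = min(min_sep, float(cdist(groups[i], groups[j]).min()))
    if max_diam == 0.0:
        return float("inf")
    return min_sep / max_diam


@dataclass
class QuantizationConfig:
    """Tunables of the quantization stage."""

    n_components: int = 4
    tol: float = 1e-6
    max_iter: int = 200
    variance_floor: float = 1e-2
    k_range: tuple[int, int] = (3, 8)
    subsample_size: int = 2000
    semantic_prototypes: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SEMANTIC_PROTOTYPES)
    )


def fit_tile_gmms(tile: RGBTile, config: QuantizationConfig, seed: int = 0) -> list[ChannelGMM]:
    """Fit one mixture per RGB channel on all tile pixels."""
    gmms = []
    for j, ch in enumerate("RGB"):
        gmms.append(
            fit_channel_gmm(
                tile.pixels[..., j].ravel(),
                n_components=config.n_components,
                tol=config.tol,
                max_iter=config.max_iter,
                seed=seed + j,
                variance_floor=config.variance_floor,
                channel=ch,
            )
        )
    return gmms


def select_num_classes(
    tile: RGBTile,
    k_range: Optional[tuple[int, int]] = None,
    subsample_size: Optional[int] = None,
    seed: int = 0,
    config: Optional[QuantizationConfig] = None,
) -> tuple[int, QuantizationScheme]:
    """Pick the class count maximizing the Dunn index of the quantized
    pixel subsample; ties break toward the smaller K."""
    config = config or QuantizationConfig()
    lo, hi = k_range or config.k_range
    if lo < 2 or hi > 10:
        raise ValueError("k_range must lie within [2, 10]")
    nsub = subsample_size or config.subsample_size
    if nsub < 1000:
        raise ValueError("subsample_size must be >= 1000")
    gmms = fit_tile_gmms(tile, config, seed=seed)
    rng = np.random.default_rng(seed)
    flat = tile.pixels.reshape(-1, 3).astype(float)
    idx = rng.choice(len(flat), size=min(nsub, len(flat)), replace=False)
    sample = flat[idx]

    best: tuple[float, int, QuantizationScheme] | None = None
    last_err: Optional[Exception] = None
    for K in range(lo, hi + 1):
        try:
            scheme = derive_thresholds(gmms, K)
        except ThresholdError as err:
            last_err = err
            continue
        d = cdist(sample, scheme.centroids, metric="sqeuclidean")
        lab = d.argmin(axis=1)
        if len(np.unique(lab)) < 2:
            continue
        score = dunn_index(sample, lab)
        if best is None or score > best[0]:
            best = (score, K, scheme)
    if best is None:
        raise last_err or ThresholdError("no feasible K in range")
    return best[1], best[2]


def annotate_segments(
    labels: np.ndarray,
    scheme: QuantizationScheme,
    prototypes: Optional[dict[int, tuple[float, float, float]]] = None,
) -> SemanticMap:
    """Map each quantization class to the semantic tissue class whose stain
    prototype is nearest to the class centroid in RGB."""
    prototypes = prototypes or DEFAULT_SEMANTIC_PROTOTYPES
    codes = list(prototypes)
    proto = np.array([prototypes[c] for c in codes], dtype=float)
    d = cdist(scheme.centroids, proto)
    mapping = {k: codes[int(d[k].argmin())] for k in range(scheme.K)}
    lut = np.array([mapping[k] for k in range(scheme.K)], dtype=np.int8)
    return SemanticMap(labels=lut[labels], provenance=mapping)
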