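"""Energy assembly and exact minimization by min-cut, plus the per-slice
volume segmentation pipeline.

The energy over binary labelings L (cau/back) is

    E(L) = sum_p U_p(L_p) + delta * sum_{p,q} B_{p,q} [L_p != L_q],

with hard seed constraints: every caudate seed must be labeled cau and every
background seed back. All B_{p,q} >= 0, so the standard two-terminal graph
construction is submodular and the min cut is a global minimizer. Seed
pixels get a terminal capacity K = 1 + delta * max_p sum_q B_{p,q}, which
exceeds any alternative cut through the pixel.

The solver delegates max-flow to scipy (Dinic). scipy works on int32
capacities, so the float capacities are scaled by (2^31 - 1) / bound, where
bound is an a-priori upper bound on the min-cut value (the all-background
seedless cut plus all n-links); the reported energy is then recomputed in
float from the returned labeling, so rounding in the flow network cannot
reach the energy bookkeeping. A brute-force enumerator over <= 20 free
pixels serves as an independent oracle for tiny instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_flow

from .boundary import (
    BoundaryPotentials,
    boundary_potentials,
    edgeness_map,
    estimate_sigma_beta,
    gaussian_derivatives,
    select_scales,
)
from .core import BinaryMask, CaudateCutConfig, SliceImage, VolumeImage, preprocess_slice
from .seeds import SeedSet, init_seeds
from .unary import (
    TrainedPixelClassifier,
    UnaryPotentials,
    combine_unary,
    fit_seed_intensity_model,
    intensity_model_from_levels,
    supervised_potentials,
    unsupervised_potentials,
)

LABEL_CAU = True
LABEL_BACK = False


@dataclass(frozen=True)
class SegGraph:
    """Two-terminal pixel graph: t-link capacities per pixel and n-link
    capacities per neighbor pair (already scaled by delta)."""

    shape: tuple[int, int]
    cap_source: np.ndarray  # S -> p, cut when p labeled back: U_p(back) or K
    cap_sink: np.ndarray    # p -> T, cut when p labeled cau: U_p(cau) or K
    nlinks: dict[tuple[int, int], np.ndarray]
    K: float
    delta: float
    unary: UnaryPotentials
    boundary: BoundaryPotentials
    seeds: SeedSet


@dataclass(frozen=True)
class SegmentationResult:
    """A labeling with its exactly recomputed energy."""

    labels: np.ndarray  # boolean grid, True = cau
    energy: float
    seeds: SeedSet
    delta: float


def evaluate_energy(
    labels: np.ndarray,
    unary: UnaryPotentials,
    boundary: BoundaryPotentials,
    delta: float,
) -> float:
    """E(L) = sum_p U_p(L_p) + delta * sum_{p,q} B_{p,q} [L_p != L_q]."""
    lab = np.asarray(labels, dtype=bool)
    e = float(np.where(lab, unary.cau, unary.back).sum())
    for (dy, dx), w in boundary.weights.items():
        H, W = boundary.shape
        lp = lab[: H - dy, max(0, -dx) : W - max(0, dx)]
        lq = lab[dy:, max(0, dx) : W - max(0, -dx)]
        e += delta * float(w[lp != lq].sum())
    return e


def build_graph(
    unary: UnaryPotentials,
    boundary: BoundaryPotentials,
    seeds: SeedSet,
    delta: float,
) -> SegGraph:
    """Assemble the seeded two-terminal graph for E(L) = U(L) + delta B(L)."""
    if unary.shape != boundary.shape or unary.shape != seeds.shape:
        raise ValueError("unary, boundary and seed shapes must agree")
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if np.any(seeds.cau & seeds.back):
        raise ValueError("a pixel cannot be both caudate and background seed")

    K = 1.0 + delta * float(boundary.neighbor_sum().max(initial=0.0))
    cap_source = np.where(seeds.cau, K, np.where(seeds.back, 0.0, unary.back))
    cap_sink = np.where(seeds.back, K, np.where(seeds.cau, 0.0, unary.cau))
    nlinks = {off: delta * w for off, w in boundary.weights.items()}
    return SegGraph(
        shape=unary.shape,
        cap_source=cap_source,
        cap_sink=cap_sink,
        nlinks=nlinks,
        K=K,
        delta=delta,
        unary=unary,
        boundary=boundary,
        seeds=seeds,
    )


def solve_min_cut(graph: SegGraph) -> SegmentationResult:
    """Global minimizer of the seeded energy via max-flow/min-cut.

    Pixels reachable from the source in the residual network are labeled
    cau. Deterministic for fixed input.
    """
    H, W = graph.shape
    n_pix = H * W
    S, T = n_pix, n_pix + 1

    rows, cols, caps = [], [], []

    def add(u, v, c):
        rows.append(u)
        cols.append(v)
        caps.append(c)

    idx = np.arange(n_pix).reshape(H, W)
    # Capacity scaling bound: a feasible cut (all pixels on one side, seeds
    # aside) costs at most sum of min t-links + all n-links + seed slack.
    bound = float(np.minimum(graph.cap_source, graph.cap_sink).sum())
    for w in graph.nlinks.values():
        bound += float(w.sum())
    bound = max(bound, 1e-12)
    scale = (2**31 - 1) / bound

    def q(x):
        # Capacities above the cut bound act as infinity; clamp to int32 max
        # so seed capacities K cannot overflow the scaled network.
        return np.minimum(np.round(x * scale), 2**31 - 1).astype(np.int64)

    src = q(graph.cap_source).ravel()
    snk = q(graph.cap_sink).ravel()
    for p in range(n_pix):
        if src[p] > 0:
            add(S, p, src[p])
        if snk[p] > 0:
            add(p, T, snk[p])
    for (dy, dx), w in graph.nlinks.items():
        wq = q(w)
        p_idx = idx[: H - dy, max(0, -dx) : W - max(0, dx)].ravel()
        q_idx = idx[dy:, max(0, dx) : W - max(0, -dx)].ravel()
        wf = wq.ravel()
        keep = wf > 0
        for pi, qi, cw in zip(p_idx[keep], q_idx[keep], wf[keep]):
            add(pi, qi, cw)
            add(qi, pi, cw)

    m = csr_matrix(
        (np.array(caps, dtype=np.int64), (np.array(rows), np.array(cols))),
        shape=(n_pix + 2, n_pix + 2),
    )
    res = maximum_flow(m, S, T)
    residual = m - res.flow
    # BFS from source over positive residual capacity -> source side = cau.
    reach = np.zeros(n_pix + 2, dtype=bool)
    reach[S] = True
    frontier = [S]
    indptr, indices = residual.indptr, residual.indices
    data = residual.data
    while frontier:
        nxt = []
        for u in frontier:
            for k in range(indptr[u], indptr[u + 1]):
                v = indices[k]
                if data[k] > 0 and not reach[v]:
                    reach[v] = True
                    nxt.append(v)
        frontier = nxt
    labels = reach[:n_pix].reshape(H, W)
    energy = evaluate_energy(labels, graph.unary, graph.boundary, graph.delta)
    return SegmentationResult(labels=labels, energy=energy, seeds=graph.seeds, delta=graph.delta)


def brute_force_segment(
    unary: UnaryPotentials,
    boundary: BoundaryPotentials,
    seeds: SeedSet,
    delta: float,
    max_free: int = 20,
) -> SegmentationResult:
    """Exhaustive-enumeration oracle for tiny instances (<= 20 free pixels).

    Ties are broken toward fewer cau pixels, then lexicographically on the
    row-major label string (cau = 1).
    """
    free = ~(seeds.cau | seeds.back)
    n_free = int(free.sum())
    if n_free > max_free:
        raise ValueError(f"{n_free} free pixels exceed the {max_free}-pixel oracle limit")
    free_pos = np.argwhere(free)
    base = seeds.cau.copy()
    best = None
    for bits in itertools.product((False, True), repeat=n_free):
        lab = base.copy()
        for (y, x), b in zip(free_pos, bits):
            lab[y, x] = b
        e = evaluate_energy(lab, unary, boundary, delta)
        key = (e, int(lab.sum()), tuple(lab.ravel().astype(int)))
        if best is None or key < best[0]:
            best = (key, lab)
    return SegmentationResult(labels=best[1], energy=best[0][0], seeds=seeds, delta=delta)


# ---------------------------------------------------------------------------
# Per-slice pipeline and volume orchestration


def segment_slice(
    img: SliceImage,
    prior: np.ndarray,
    clf: TrainedPixelClassifier | None,
    config: CaudateCutConfig,
    preprocessed: bool = False,
    intensity_model=None,
) -> SegmentationResult:
    """Segment one slice given its raw image and 2-D prior mask.

    Runs the full chain: preprocessing, seed initialization, unsupervised +
    supervised unary terms, scale-adaptive boundary terms with edgeness
    modulation, graph assembly and exact min-cut. With ``clf`` None the
    supervised term is skipped (unsupervised-only cut). A pre-fitted
    ``intensity_model`` (e.g. pooled over a volume's seeds) overrides the
    per-slice seed histogram.
    """
    work = img if preprocessed else preprocess_slice(img, config)
    seeds = init_seeds(prior, config.ke, config.kd)

    model = intensity_model
    if model is None:
        model = fit_seed_intensity_model(
            work, seeds.cau, config.epsilon_prob, config.hist_smooth_sd
        )
    uu = unsupervised_potentials(work, model)
    if clf is not None:
        su = supervised_potentials(work, clf)
        unary = combine_unary(uu, su)
    else:
        unary = uu

    scales = select_scales(work, config.scale_grid)
    deriv = gaussian_derivatives(work, scales, config.lindeberg_ell)
    sigma, beta = estimate_sigma_beta(
        work, deriv, config.neighborhood, config.sigma_estimator
    )
    edges = None
    if config.boundary_mode != "off":
        edges = edgeness_map(
            work, config.edge_threshold_grid, config.edge_scale_grid, config.edge_smooth_sd
        )
    bpots = boundary_potentials(
        work,
        deriv,
        edges,
        config.alpha,
        sigma,
        beta,
        neighborhood=config.neighborhood,
        mode=config.boundary_mode,
        distance_exponent=config.distance_exponent,
    )
    graph = build_graph(unary, bpots, seeds, config.delta)
    return solve_min_cut(graph)


def segment_volume(
    vol: VolumeImage,
    prior: BinaryMask,
    clf: TrainedPixelClassifier | None,
    config: CaudateCutConfig | None = None,
) -> tuple[BinaryMask, list[SegmentationResult | None]]:
    """Segment a volume slice by slice against a 3-D prior mask.

    The caudate intensity model is fitted once per volume from the pooled
    seed graylevels of all usable slices — thin end slices whose eroded
    seed sets are tiny still get a well-populated histogram. Slices with an
    empty prior get an all-background label plane. Returns the stacked 3-D
    mask and the per-slice results (None where skipped).
    """
    config = config or CaudateCutConfig()
    if prior.shape != vol.shape:
        raise ValueError("prior mask shape must match the volume")
    if prior.count() == 0:
        raise ValueError("prior mask is empty")
    pmask = prior.astype_bool()

    # First pass: preprocess, seed, and pool seed graylevels.
    prepped: dict[int, SliceImage] = {}
    seed_levels = []
    for k in range(vol.n_slices):
        if not pmask[:, :, k].any():
            continue
        work = preprocess_slice(vol.get_slice(k), config)
        prepped[k] = work
        seeds_k = init_seeds(pmask[:, :, k], config.ke, config.kd)
        seed_levels.append(work.pixels[seeds_k.cau])
    model = intensity_model_from_levels(
        np.concatenate(seed_levels), config.epsilon_prob, config.hist_smooth_sd
    )

    out = np.zeros(vol.shape, dtype=np.uint8)
    results: list[SegmentationResult | None] = []
    for k in range(vol.n_slices):
        if k not in prepped:
            results.append(None)
            continue
        res = segment_slice(
            prepped[k],
            pmask[:, :, k],
            clf,
            config,
            preprocessed=True,
            intensity_model=model,
        )
        out[:, :, k] = res.labels.astype(np.uint8)
        results.append(res)
    return BinaryMask(out, vol.voxel_dims), results
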