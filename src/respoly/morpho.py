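"""Landmark-based geometric morphometrics.

Reads TPS landmark files, performs a generalized Procrustes (full Procrustes)
fit, removes the allometric shape component by pooled within-group regression
on centroid size, and quantifies two-group shape divergence with a linear
discriminant analysis whose significance is assessed by label permutation.

Shape variables are Procrustes tangent coordinates. A two-group discriminant
is invariant to any invertible linear change of basis of the shape variables,
so tangent coordinates yield the same discriminant scores as a partial-warp +
uniform-component basis would; the equivalence is exercised in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

EXPECTED_LANDMARKS = {"body": 19, "chela": 7}


@dataclass
class LandmarkConfig:
    """One specimen's ordered 2-D landmarks for one structure."""

    specimen_id: str
    structure: str          # "body" | "chela"
    coords: np.ndarray      # k x 2
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a k x 2 matrix")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: missing/non-finite coordinates")
        expected = EXPECTED_LANDMARKS.get(self.structure)
        if expected is not None and self.coords.shape[0] != expected:
            raise ValueError(
                f"{self.specimen_id}: structure {self.structure!r} expects "
                f"{expected} landmarks, got {self.coords.shape[0]}")


@dataclass
class AlignedShapes:
    specimens: List[str]
    procrustes_coords: np.ndarray   # n x 2k, unit centroid size, rotated
    consensus: np.ndarray           # k x 2, unit centroid size
    centroid_sizes: np.ndarray      # n
    tangent_coords: np.ndarray      # n x 2k
    n_iterations: int = 0

    @property
    def k(self) -> int:
        return self.consensus.shape[0]


@dataclass
class DfaResult:
    axis: np.ndarray            # 2k, discriminant direction in shape space
    scores: np.ndarray          # n, grand mean 0, unit pooled within-group var
    groups: Tuple[str, str]
    group_means: Dict[str, float]
    t_square: float
    p_value: float
    cv_accuracy: float
    extreme_shapes: Dict[str, np.ndarray] = field(default_factory=dict)
    n_permutations: int = 0


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def read_tps(path) -> List[LandmarkConfig]:
    """Parse a TPS landmark file (``LM=``, coordinate lines, ``ID=``, ``SCALE=``).

    Coordinates are multiplied by SCALE when present (converting digitizer
    pixels to physical units). The structure is inferred from the landmark
    count when it matches a known structure, else left as ``"unknown"``.
    """
    configs: List[LandmarkConfig] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ValueError(f"{path}: line {i + 1}: expected 'LM=' record, got {line!r}")
        k = int(line.split("=", 1)[1])
        coords = np.empty((k, 2))
        for j in range(k):
            i += 1
            if i >= n_lines:
                raise ValueError(f"{path}: truncated record at line {i + 1}")
            parts = lines[i].split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {i + 1}: expected 'x y', got {lines[i]!r}")
            coords[j] = [float(parts[0]), float(parts[1])]
        spec_id, scale = "", None
        i += 1
        while i < n_lines:
            line = lines[i].strip()
            if not line or line.upper().startswith("LM="):
                break
            key, _, value = line.partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = value.strip()
            elif key == "IMAGE" and not spec_id:
                spec_id = value.strip()
            elif key == "SCALE":
                scale = float(value)
            i += 1
        if scale is not None:
            coords = coords * scale
        structure = {v: s for s, v in EXPECTED_LANDMARKS.items()}.get(k, "unknown")
        configs.append(LandmarkConfig(spec_id or f"spec_{len(configs)}",
                                      structure, coords, scale))
    if configs:
        counts = {c.coords.shape[0] for c in configs}
        if len(counts) > 1:
            bad = [c.specimen_id for c in configs
                   if c.coords.shape[0] != configs[0].coords.shape[0]]
            raise ValueError(
                f"{path}: inconsistent landmark counts {sorted(counts)}; "
                f"first offending record(s): {bad[:3]}")
    return configs


def write_tps(configs: Sequence[LandmarkConfig], path) -> None:
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.coords.shape[0]}\n")
            for x, y in c.coords:
                fh.write(f"{x:.10f} {y:.10f}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# Superimposition
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """sqrt of summed squared landmark distances from their centroid."""
    coords = config.coords if isinstance(config, LandmarkConfig) else np.asarray(config, float)
    centered = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincide (CS=0)")
    return cs


def _optimal_rotation(x: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate ``x`` (k x 2) onto ``target`` minimizing squared distance.

    Closed-form 2-D solution; reflections are not allowed (landmarks are
    digitized consistently from the dorsal view).
    """
    num = float(x[:, 0] @ target[:, 1] - x[:, 1] @ target[:, 0])
    den = float((x * target).sum())
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return x @ rot.T


def full_procrustes_fit(configs: Sequence[LandmarkConfig],
                        tol: float = 1e-10,
                        max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes analysis of a sample of configurations.

    Each configuration is centered, scaled to unit centroid size, and
    iteratively rotated to the running consensus; the consensus (mean shape,
    renormalized to unit CS) is the fixed point of the fit. Tangent
    coordinates are the aligned coordinates orthogonally projected onto the
    tangent space at the consensus.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    k = configs[0].coords.shape[0]
    for c in configs:
        if c.coords.shape[0] != k:
            raise ValueError(
                f"landmark count mismatch: {c.specimen_id} has "
                f"{c.coords.shape[0]}, expected {k}")
    n = len(configs)
    sizes = np.array([centroid_size(c) for c in configs])
    shapes = np.stack([
        (c.coords - c.coords.mean(axis=0)) / s
        for c, s in zip(configs, sizes)
    ])

    consensus = shapes[0].copy()
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = np.stack([_optimal_rotation(s, consensus) for s in shapes])
        new_consensus = aligned.mean(axis=0)
        new_consensus = new_consensus / np.sqrt((new_consensus**2).sum())
        delta = float(np.abs(new_consensus - consensus).max())
        consensus = new_consensus
        shapes = aligned
        if delta < tol:
            break
    else:
        raise RuntimeError(f"GPA did not converge: final delta {delta:.3e}")

    flat = shapes.reshape(n, 2 * k)
    c_vec = consensus.reshape(-1)
    c_vec = c_vec / np.linalg.norm(c_vec)
    tangent = flat - np.outer(flat @ c_vec, c_vec)

    return AlignedShapes(
        specimens=[c.specimen_id for c in configs],
        procrustes_coords=flat,
        consensus=consensus,
        centroid_sizes=sizes,
        tangent_coords=tangent,
        n_iterations=n_iter,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both are centered and scaled to unit centroid size, then ``b`` is
    optimally rotated onto ``a``; the distance is the residual Euclidean norm.
    """
    a = np.asarray(a, float); b = np.asarray(b, float)
    a = a - a.mean(axis=0); a = a / np.sqrt((a**2).sum())
    b = b - b.mean(axis=0); b = b / np.sqrt((b**2).sum())
    return float(np.linalg.norm(_optimal_rotation(b, a) - a))


# ---------------------------------------------------------------------------
# Allometry
# ---------------------------------------------------------------------------

def allometry_correct(aligned: AlignedShapes,
                      groups: Sequence[str],
                      log_size: bool = False) -> np.ndarray:
    """Remove the allometric shape component by pooled within-group regression.

    The common slope of shape on centroid size is estimated from group-mean-
    centered predictor and response (so group differences do not leak into the
    slope); residuals are ``shape - slope * CS``, grand-centered. Group mean
    differences are retained because group is not a regressor.
    """
    groups = np.asarray(groups)
    if len(groups) != len(aligned.specimens):
        raise ValueError("one group label per specimen required")
    for g in np.unique(groups):
        if (groups == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 specimens")
    y = aligned.tangent_coords
    cs = np.log(aligned.centroid_sizes) if log_size else aligned.centroid_sizes

    cs_c = cs.astype(float).copy()
    y_c = y.copy()
    for g in np.unique(groups):
        m = groups == g
        cs_c[m] -= cs_c[m].mean()
        y_c[m] -= y_c[m].mean(axis=0)
    ss = float(cs_c @ cs_c)
    if ss < 1e-12:
        warnings.warn("centroid size is constant within groups; slope set to 0")
        slope = np.zeros(y.shape[1])
    else:
        slope = (cs_c[:, None] * y_c).sum(axis=0) / ss
    resid = y - np.outer(cs, slope)
    return resid - resid.mean(axis=0)


# ---------------------------------------------------------------------------
# Discriminant analysis
# ---------------------------------------------------------------------------

def _pca_reduce(x: np.ndarray, rtol: float = 1e-12) -> Tuple[np.ndarray, np.ndarray]:
    """Project onto principal axes with eigenvalue > rtol * max eigenvalue.

    Shape tangent space has rank <= 2k - 4, so the raw covariance is always
    singular; this removes the null directions before the discriminant fit.
    """
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > rtol * evals.max()
    basis = evecs[:, keep][:, ::-1]
    return xc @ basis, basis


def _t_square(y: np.ndarray, mask1: np.ndarray) -> float:
    n1 = int(mask1.sum()); n2 = y.shape[0] - n1
    m1 = y[mask1].mean(axis=0); m2 = y[~mask1].mean(axis=0)
    d = m2 - m1
    s1 = y[mask1] - m1; s2 = y[~mask1] - m2
    sp = (s1.T @ s1 + s2.T @ s2) / (n1 + n2 - 2)
    sol = np.linalg.solve(sp, d)
    return float(n1 * n2 / (n1 + n2) * d @ sol)


def dfa(residuals: np.ndarray,
        labels: Sequence[str],
        n_permutations: int = 10_000,
        seed: int = 0,
        consensus: Optional[np.ndarray] = None,
        positive_group: str = "pelagic",
        amplification: float = 10.0) -> DfaResult:
    """Two-group discriminant analysis of shape variables.

    The shape space is first reduced by PCA (rank tolerance 1e-12 relative),
    then a linear discriminant is computed from the pooled within-group
    covariance. Significance of the group separation (Hotelling T^2) is
    assessed by a seeded label-permutation test; classification performance by
    leave-one-out cross-validation. Scores are centered to grand mean 0 and
    scaled to unit pooled within-group variance; the axis is oriented so the
    ``positive_group`` mean is positive.
    """
    residuals = np.asarray(residuals, float)
    labels = np.asarray(labels)
    uniq = sorted(np.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    for g in uniq:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 specimens")

    y, basis = _pca_reduce(residuals)
    n, p = y.shape
    if n <= p + 2:
        raise ValueError(
            f"too few specimens ({n}) for {p} retained shape dimensions; "
            "collect more specimens or reduce dimensionality")
    mask1 = labels == uniq[0]
    n1 = int(mask1.sum()); n2 = n - n1

    m1 = y[mask1].mean(axis=0); m2 = y[~mask1].mean(axis=0)
    s1 = y[mask1] - m1; s2 = y[~mask1] - m2
    sp = (s1.T @ s1 + s2.T @ s2) / (n - 2)
    try:
        w = np.linalg.solve(sp, m2 - m1)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular pooled within-group covariance; more specimens are "
            "needed for this many shape dimensions") from err

    # unit pooled within-group variance of the scores
    w = w / np.sqrt(float(w @ sp @ w))
    scores = y @ w
    scores = scores - scores.mean()
    ref = positive_group if positive_group in uniq else uniq[1]
    if scores[labels == ref].mean() < 0:
        w = -w
        scores = -scores

    t2_obs = float(n1 * n2 / n * (m2 - m1) @ np.linalg.solve(sp, m2 - m1))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _t_square(y, mask1[perm]) >= t2_obs:
            count += 1
    p_value = (count + 1) / (n_permutations + 1)

    # leave-one-out CV
    correct = 0
    for i in range(n):
        keep = np.ones(n, bool); keep[i] = False
        yi, li = y[keep], mask1[keep]
        mm1 = yi[li].mean(axis=0); mm2 = yi[~li].mean(axis=0)
        r1 = yi[li] - mm1; r2 = yi[~li] - mm2
        spi = (r1.T @ r1 + r2.T @ r2) / (n - 3)
        wi = np.linalg.solve(spi, mm2 - mm1)
        score = (y[i] - (mm1 + mm2) / 2) @ wi
        predicted_first = score < 0
        correct += int(predicted_first == mask1[i])
    cv_accuracy = correct / n

    axis_full = basis @ w
    extreme = {}
    if consensus is not None:
        k = consensus.shape[0]
        disp = amplification * axis_full.reshape(k, 2)
        extreme = {
            "negative": consensus - disp,
            "positive": consensus + disp,
        }

    group_means = {g: float(scores[labels == g].mean()) for g in uniq}
    return DfaResult(
        axis=axis_full,
        scores=scores,
        groups=(uniq[0], uniq[1]),
        group_means=group_means,
        t_square=t2_obs,
        p_value=p_value,
        cv_accuracy=cv_accuracy,
        extreme_shapes=extreme,
        n_permutations=n_permutations,
    )
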