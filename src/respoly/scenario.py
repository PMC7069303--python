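"""Study scenario configuration for the synthetic-data generator.

A :class:`ScenarioConfig` fixes every quantity the generator needs: lake and
sample-size structure, mean landmark shapes and the habitat/sex deformations
applied to them, isotope means and noise scales, microsatellite allele
frequencies and the Balding-Nichols divergence parameters, and the lake
environment model. The defaults emulate the field study this pipeline
reproduces: 7 lakes with ~20 crayfish per habitat, 19 body / 7 chela
landmarks, 14 microsatellite loci with 2-11 alleles, near-equal trophic
position between habitats and a small littoral-reliance difference, and no
genetic divergence between habitats (``theta_habitat = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np

N_BODY_LANDMARKS = 19
N_CHELA_LANDMARKS = 7

HABITATS = ("littoral", "pelagic")
SEXES = ("F", "M")


def _unit_cs(shape: np.ndarray) -> np.ndarray:
    """Center a k x 2 configuration and scale it to unit centroid size."""
    shape = np.asarray(shape, dtype=float)
    shape = shape - shape.mean(axis=0)
    cs = np.sqrt((shape**2).sum())
    return shape / cs


def body_mean_shape() -> np.ndarray:
    """Stylized 19-landmark crayfish body (cephalothorax + abdomen), unit CS.

    Anterior is +x; the configuration is bilaterally symmetric about the
    x-axis: rostrum tip, paired eyes, paired carapace outline points, a
    mid-dorsal point, paired cervical-groove points, three paired abdominal
    segments, and the telson tip.
    """
    pts = [
        (1.00, 0.00),              # rostrum tip
        (0.85, 0.12), (0.85, -0.12),   # eyes
        (0.70, 0.25), (0.70, -0.25),   # carapace anterior margin
        (0.50, 0.15), (0.50, -0.15),   # cervical groove
        (0.35, 0.30), (0.35, -0.30),   # carapace widest point
        (0.35, 0.00),              # mid-dorsal carapace
        (0.00, 0.28), (0.00, -0.28),   # carapace posterior margin
        (-0.30, 0.22), (-0.30, -0.22),  # abdominal segment 1
        (-0.60, 0.16), (-0.60, -0.16),  # abdominal segment 3
        (-0.85, 0.10), (-0.85, -0.10),  # abdominal segment 5
        (-1.00, 0.00),             # telson tip
    ]
    return _unit_cs(np.array(pts))


def chela_mean_shape() -> np.ndarray:
    """Stylized 7-landmark chela propodus outline, unit centroid size."""
    pts = [
        (0.00, 0.15), (0.00, -0.15),   # propodus base
        (0.50, 0.25), (0.50, -0.25),   # propodus widest point
        (1.00, 0.08),              # dactyl articulation
        (1.00, -0.20),             # pollex base
        (1.35, 0.00),              # pollex tip
    ]
    return _unit_cs(np.array(pts))


def _normalize_pattern(d: np.ndarray, mean_shape: np.ndarray) -> np.ndarray:
    """Center a deformation, remove its similarity components, unit-norm it.

    Components along the mean shape (scaling) and its 90-degree rotation
    (rotation) are projected out: a Procrustes fit silently removes them, so
    leaving them in would make the nominal effect magnitude overstate the
    realized shape change.
    """
    d = d - d.mean(axis=0)
    m = _unit_cs(mean_shape).reshape(-1)
    rot = (_unit_cs(mean_shape) @ np.array([[0.0, 1.0], [-1.0, 0.0]])).reshape(-1)
    rot = rot / np.linalg.norm(rot)
    v = d.reshape(-1)
    v = v - (v @ m) * m - (v @ rot) * rot
    v = v / np.linalg.norm(v)
    return v.reshape(d.shape)


def streamlining_pattern(mean_shape: np.ndarray) -> np.ndarray:
    """Unit-norm deformation: elongate along the body axis, narrow laterally.

    This is the littoral->pelagic contrast reported for both structures:
    pelagic individuals are more streamlined, littoral ones stockier.
    """
    x, y = mean_shape[:, 0], mean_shape[:, 1]
    return _normalize_pattern(np.column_stack([0.5 * x, -y]), mean_shape)


def sex_pattern(mean_shape: np.ndarray) -> np.ndarray:
    """Unit-norm deformation for sexual dimorphism: widen the posterior part."""
    x, y = mean_shape[:, 0], mean_shape[:, 1]
    return _normalize_pattern(np.column_stack([-0.2 * x, y * (x < 0.2)]),
                              mean_shape)


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study.

    Shape effects are expressed as ``magnitude * unit-norm pattern`` in units
    of Procrustes (unit-centroid-size) coordinates; landmark noise is the
    isotropic per-coordinate SD on the same scale. Isotope noise SDs are in
    per-mil; ``theta_lake``/``theta_habitat`` are Balding-Nichols divergence
    parameters (theta ~ expected FST).
    """

    n_lakes: int = 7
    n_per_habitat: int = 20

    # --- landmarks ---
    mean_shape_body: np.ndarray = field(default_factory=body_mean_shape)
    mean_shape_chela: np.ndarray = field(default_factory=chela_mean_shape)
    # magnitudes of the unit-norm deformation patterns, Procrustes units
    habitat_effect_body: float = 0.0081
    habitat_effect_chela: float = 0.0046
    sex_effect_body: float = 0.008
    sex_effect_chela: float = 0.010
    allometric_slope: float = 0.004   # shape shift per unit log centroid size
    landmark_noise_sd: float = 0.010
    # centroid size ~ LogNormal(meanlog, sdlog), in mm
    size_meanlog: float = np.log(48.0)
    size_sdlog: float = 0.15

    # --- isotopes ---
    tp_true: Dict[str, float] = field(
        default_factory=lambda: {"littoral": 3.00, "pelagic": 3.05})
    lr_true: Dict[str, float] = field(
        default_factory=lambda: {"littoral": 0.35, "pelagic": 0.33})
    d15n_noise_sd: float = 2.0
    d13c_noise_sd: float = 2.4
    baseline_rep_sd: float = 0.5       # among-location replicate SD, per mil
    baseline_lake_sd: float = 1.0      # among-lake baseline SD, per mil
    baseline_centers: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "periphyton": {"d13C": -20.0, "d15N": 2.0},
        "litter": {"d13C": -28.5, "d15N": 0.0},
        "zooplankton": {"d13C": -30.0, "d15N": 6.0},
    })

    # --- genotypes ---
    n_loci: int = 14
    ancestral_freqs: Optional[List[np.ndarray]] = None  # derived from seed if None
    theta_lake: float = 0.05
    theta_habitat: float = 0.0

    # --- environment (16-lake habitat-use survey) ---
    env_n_lakes: int = 16
    cpue_intercept: float = 1.0        # sqrt(pelagic CPUE) at littoral CPUE 0
    cpue_slope: float = 0.5            # sqrt(pelagic CPUE) per littoral CPUE
    cpue_noise_sd: float = 0.45        # on the sqrt scale

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_habitat < 2:
            raise ValueError("n_per_habitat must be >= 2")
        for name in ("landmark_noise_sd", "d15n_noise_sd", "d13c_noise_sd",
                     "baseline_rep_sd", "baseline_lake_sd", "cpue_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("theta_lake", "theta_habitat"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must be in [0, 1)")
        for hab, v in self.lr_true.items():
            if not (0 < v < 1):
                raise ValueError(f"lr_true[{hab!r}]={v} must lie in (0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.ancestral_freqs is not None:
            for i, p in enumerate(self.ancestral_freqs):
                p = np.asarray(p, float)
                if not np.isclose(p.sum(), 1.0):
                    raise ValueError(f"ancestral_freqs[{i}] must sum to 1")

    @property
    def lakes(self) -> List[str]:
        return [chr(ord("A") + i) for i in range(self.n_lakes)]

    @property
    def env_lakes(self) -> List[str]:
        return [chr(ord("A") + i) for i in range(self.env_n_lakes)]

    def with_(self, **kw) -> "ScenarioConfig":
        return replace(self, **kw)


def default_ancestral_freqs(n_loci: int, seed: int) -> List[np.ndarray]:
    """Per-locus ancestral allele-frequency vectors.

    Allele counts are spread over 2-11 (the range observed at the study's 14
    microsatellites); frequencies are symmetric-Dirichlet draws.
    """
    rng = np.random.default_rng(seed)
    counts = list(2 + (np.arange(n_loci) * 9) // max(n_loci - 1, 1))
    freqs = []
    for k in counts:
        p = rng.dirichlet(np.full(k, 2.0))
        p = np.clip(p, 0.02, None)
        freqs.append(p / p.sum())
    return freqs
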