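"""Synthetic study generator.

Emulates the five inputs of the field study — landmark files, specimen
metadata, isotope samples with baselines, GENEPOP genotypes, and the per-lake
environment table — from a :class:`~respoly.scenario.ScenarioConfig` with
known habitat, sex and lake structure, so every downstream stage has a
parameter-recovery test. All generators are deterministic functions of
``cfg.seed`` (independent substreams per dataset, so generating one dataset
never perturbs another).
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .morpho import LandmarkConfig, write_tps
from .popgen import GenotypeTable, write_genepop
from .scenario import (HABITATS, SEXES, ScenarioConfig, default_ancestral_freqs,
                       sex_pattern, streamlining_pattern)

# substream ids: one per dataset
_STREAMS = {"specimens": 1, "body": 2, "chela": 3, "isotopes": 4,
            "genotypes": 5, "environment": 6}


def _rng(cfg: ScenarioConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[stream]])


def allometry_pattern(mean_shape: np.ndarray) -> np.ndarray:
    """Unit-norm shape change per unit log centroid size: larger animals
    relatively broader in the cephalothorax."""
    from .scenario import _normalize_pattern
    x, y = mean_shape[:, 0], mean_shape[:, 1]
    return _normalize_pattern(np.column_stack([-0.3 * x, y * (x > 0)]),
                              mean_shape)


def generate_specimens(cfg: ScenarioConfig) -> pd.DataFrame:
    """Specimen metadata: lake, habitat, sex, carapace length, chela size.

    The same individuals carry landmarks, isotopes and genotypes, as in the
    field protocol (each trapped crayfish was photographed, sampled for
    muscle, and genotyped).
    """
    rng = _rng(cfg, "specimens")
    rows = []
    for lake in cfg.lakes:
        for habitat in HABITATS:
            for i in range(cfg.n_per_habitat):
                sex = SEXES[int(rng.integers(2))]
                cl = float(np.exp(rng.normal(cfg.size_meanlog, cfg.size_sdlog)))
                chela_size = float(cl * 0.55 * np.exp(rng.normal(0, 0.10)))
                rows.append({
                    "specimen_id": f"{lake}-{habitat}-{i:03d}",
                    "lake": lake, "habitat": habitat, "sex": sex,
                    "carapace_length": cl, "chela_size": chela_size,
                })
    return pd.DataFrame(rows)


def generate_landmarks(cfg: ScenarioConfig, structure: str,
                       specimens: Optional[pd.DataFrame] = None,
                       ) -> List[LandmarkConfig]:
    """Landmark configurations for one structure (``body`` or ``chela``).

    Specimen i's pre-noise shape is
    ``mean + habitat_effect * 1[pelagic] + sex_effect * 1[female]
    + allometric_slope * (log CS_i - mean log CS)`` (all in unit-centroid-size
    Procrustes units), then scaled to the specimen's centroid size, randomly
    rotated and translated, and perturbed by isotropic Gaussian landmark
    noise proportional to the specimen's size.
    """
    if structure == "body":
        mean = cfg.mean_shape_body
        hab_mag, sex_mag = cfg.habitat_effect_body, cfg.sex_effect_body
        size_col = "carapace_length"
        expected = 19
    elif structure == "chela":
        mean = cfg.mean_shape_chela
        hab_mag, sex_mag = cfg.habitat_effect_chela, cfg.sex_effect_chela
        size_col = "chela_size"
        expected = 7
    else:
        raise ValueError(f"unknown structure {structure!r}")
    if mean.shape[0] != expected:
        raise ValueError(
            f"mean shape for {structure!r} must have {expected} landmarks, "
            f"got {mean.shape[0]}")
    if specimens is None:
        specimens = generate_specimens(cfg)

    hab_eff = hab_mag * streamlining_pattern(mean)
    sex_eff = sex_mag * sex_pattern(mean)
    allo = cfg.allometric_slope * allometry_pattern(mean)

    rng = _rng(cfg, structure)
    sizes = specimens[size_col].to_numpy(float)
    log_cs = np.log(sizes)
    log_cs_c = log_cs - log_cs.mean()

    configs = []
    for j, row in enumerate(specimens.itertuples()):
        shape = mean.copy()
        if row.habitat == "pelagic":
            shape = shape + hab_eff
        if row.sex == "F":
            shape = shape + sex_eff
        shape = shape + allo * log_cs_c[j]
        # random similarity transform, then digitization noise
        cs = sizes[j]
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s], [s, c]])
        coords = shape @ rot.T * cs + rng.normal(0, 50.0, size=2)
        coords = coords + rng.normal(0, cfg.landmark_noise_sd * cs,
                                     size=shape.shape)
        configs.append(LandmarkConfig(row.specimen_id, structure, coords))
    return configs


def generate_isotopes(cfg: ScenarioConfig,
                      specimens: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Isotope sample table: crayfish plus 3 replicate rows per baseline group.

    Crayfish d15N is drawn so the trophic-position equation recovers
    ``tp_true`` in expectation against the lake's true baseline means, and
    d13C so the littoral-reliance mixing equation recovers ``lr_true``;
    baseline replicates scatter around the lake-level values with SD
    ``baseline_rep_sd``.
    """
    if specimens is None:
        specimens = generate_specimens(cfg)
    rng = _rng(cfg, "isotopes")
    rows = []
    lake_base: Dict[str, Dict[str, Dict[str, float]]] = {}
    for lake in cfg.lakes:
        lake_base[lake] = {}
        for group, centers in cfg.baseline_centers.items():
            lake_base[lake][group] = {
                el: centers[el] + rng.normal(0, cfg.baseline_lake_sd)
                for el in ("d13C", "d15N")
            }
        for group in cfg.baseline_centers:
            for rep in range(3):
                rows.append({
                    "sample_id": f"{lake}-{group}-{rep}",
                    "group": group, "lake": lake, "habitat": None,
                    "d13C": lake_base[lake][group]["d13C"]
                    + rng.normal(0, cfg.baseline_rep_sd),
                    "d15N": lake_base[lake][group]["d15N"]
                    + rng.normal(0, cfg.baseline_rep_sd),
                })
    for row in specimens.itertuples():
        base = lake_base[row.lake]
        d15n_base = (base["periphyton"]["d15N"] + base["litter"]["d15N"]) / 2
        d15n = (d15n_base + (cfg.tp_true[row.habitat] - 1.0) * 3.4
                + rng.normal(0, cfg.d15n_noise_sd))
        gap = base["periphyton"]["d13C"] - base["zooplankton"]["d13C"]
        d13c = (base["zooplankton"]["d13C"] + cfg.lr_true[row.habitat] * gap
                + rng.normal(0, cfg.d13c_noise_sd))
        rows.append({
            "sample_id": row.specimen_id, "group": "crayfish",
            "lake": row.lake, "habitat": row.habitat,
            "d13C": d13c, "d15N": d15n,
        })
    return pd.DataFrame(rows)


def balding_nichols_freqs(p: np.ndarray, theta: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Draw descendant allele frequencies around ancestral ``p``.

    Dirichlet with concentration ``p (1 - theta) / theta``; the expected
    Weir-Cockerham theta among replicate draws equals ``theta``. ``theta = 0``
    returns ``p`` unchanged.
    """
    if theta == 0:
        return np.asarray(p, float)
    conc = np.asarray(p, float) * (1 - theta) / theta
    q = rng.dirichlet(conc)
    # guard against numerically-zero frequencies from tiny concentrations
    q = np.clip(q, 1e-9, None)
    return q / q.sum()


def generate_genotypes(cfg: ScenarioConfig,
                       specimens: Optional[pd.DataFrame] = None) -> GenotypeTable:
    """Diploid microsatellite genotypes under the neutral divergence model.

    Lake allele frequencies are Balding-Nichols draws around the ancestral
    frequencies with ``theta_lake``; habitat samples within a lake share the
    lake frequencies when ``theta_habitat = 0`` (the study's null) and are
    further-diverged draws otherwise. Genotypes are Hardy-Weinberg draws.
    """
    if specimens is None:
        specimens = generate_specimens(cfg)
    rng = _rng(cfg, "genotypes")
    freqs = cfg.ancestral_freqs
    if freqs is None:
        freqs = default_ancestral_freqs(cfg.n_loci, cfg.seed)
    if len(freqs) != cfg.n_loci:
        raise ValueError("ancestral_freqs length must equal n_loci")

    loci = [f"Pcl{li + 1:02d}" for li in range(cfg.n_loci)]
    pop_freqs: Dict[str, List[np.ndarray]] = {}
    for lake in cfg.lakes:
        lake_f = [balding_nichols_freqs(p, cfg.theta_lake, rng) for p in freqs]
        for habitat in HABITATS:
            pop_freqs[f"{lake}-{habitat}"] = [
                balding_nichols_freqs(p, cfg.theta_habitat, rng) for p in lake_f]

    n = len(specimens)
    calls = np.zeros((n, cfg.n_loci, 2), dtype=int)
    for i, row in enumerate(specimens.itertuples()):
        pf = pop_freqs[f"{row.lake}-{row.habitat}"]
        for li in range(cfg.n_loci):
            k = len(pf[li])
            calls[i, li] = rng.choice(np.arange(1, k + 1), size=2, p=pf[li])
    return GenotypeTable(
        individuals=list(specimens["specimen_id"]),
        pops=np.array([f"{l}-{h}" for l, h in
                       zip(specimens["lake"], specimens["habitat"])]),
        loci=loci, calls=calls)


def generate_environment(cfg: ScenarioConfig) -> pd.DataFrame:
    """Per-lake habitat-use survey table (the 16-lake stage of the study).

    Pelagic CPUE depends linearly on littoral CPUE on the square-root scale
    (``sqrt(pelagic) = intercept + slope * littoral + noise``); predator BPUE, littoral
    habitat proportion and invasion year are independent covariates.
    """
    if cfg.env_n_lakes < 5:
        raise ValueError("need at least 5 lakes for model fitting")
    rng = _rng(cfg, "environment")
    lakes = cfg.env_lakes
    cpue_litt = rng.gamma(2.0, 1.2, size=len(lakes)).clip(0, 4.8)
    sqrt_pel = (cfg.cpue_intercept + cfg.cpue_slope * cpue_litt
                + rng.normal(0, cfg.cpue_noise_sd, size=len(lakes)))
    cpue_pel = np.clip(sqrt_pel, 0, None) ** 2
    return pd.DataFrame({
        "lake": lakes,
        "cpue_littoral": cpue_litt,
        "cpue_pelagic": cpue_pel,
        "bpue_predators": np.exp(rng.normal(np.log(300), 0.8, size=len(lakes))),
        "pct_littoral": rng.uniform(15, 85, size=len(lakes)),
        "invasion_year": rng.integers(1995, 2008, size=len(lakes)),
    })


def generate_all(cfg: ScenarioConfig, outdir=None) -> Dict[str, object]:
    """Generate every dataset; optionally write them as study files.

    Files written under ``outdir``: ``body.tps``, ``chela.tps``,
    ``specimens.csv``, ``isotopes.csv``, ``genotypes.gen``,
    ``environment.csv``.
    """
    specimens = generate_specimens(cfg)
    data = {
        "specimens": specimens,
        "body": generate_landmarks(cfg, "body", specimens),
        "chela": generate_landmarks(cfg, "chela", specimens),
        "isotopes": generate_isotopes(cfg, specimens),
        "genotypes": generate_genotypes(cfg, specimens),
        "environment": generate_environment(cfg),
    }
    if outdir is not None:
        import os
        os.makedirs(outdir, exist_ok=True)
        write_tps(data["body"], os.path.join(outdir, "body.tps"))
        write_tps(data["chela"], os.path.join(outdir, "chela.tps"))
        specimens.to_csv(os.path.join(outdir, "specimens.csv"), index=False)
        data["isotopes"].to_csv(os.path.join(outdir, "isotopes.csv"), index=False)
        write_genepop(data["genotypes"], os.path.join(outdir, "genotypes.gen"))
        data["environment"].to_csv(os.path.join(outdir, "environment.csv"),
                                   index=False)
    return data
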