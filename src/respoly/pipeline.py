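"""End-to-end study pipeline over a (synthetic or loaded) dataset.

``run_study`` executes every stage in order — habitat-use abundance model,
geometric morphometrics with DFA per structure, trophic metrics and their
models, microsatellite diversity and F_ST, and the P_ST-vs-F_ST
classification — and returns a results dictionary the report writer, the
acceptance script and the end-to-end tests all consume.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import models, pstfst
from .isotopes import trophic_metrics
from .morpho import allometry_correct, dfa, full_procrustes_fit
from .popgen import diversity, wc_fst
from .scenario import ScenarioConfig
from .synth import generate_all

TRAITS = ("body_dfa", "chela_dfa", "trophic_position", "littoral_reliance_sqrt")


def morphometrics_stage(configs, specimens: pd.DataFrame,
                        n_permutations: int = 10_000, seed: int = 0) -> Dict:
    """GPA -> allometry correction -> two-group DFA for one structure."""
    aligned = full_procrustes_fit(configs)
    meta = specimens.set_index("specimen_id").loc[aligned.specimens]
    habitat = meta["habitat"].to_numpy()
    resid = allometry_correct(aligned, habitat)
    result = dfa(resid, habitat, n_permutations=n_permutations, seed=seed,
                 consensus=aligned.consensus)
    scores = pd.DataFrame({
        "specimen_id": aligned.specimens,
        "habitat": habitat,
        "sex": meta["sex"].to_numpy(),
        "lake": meta["lake"].to_numpy(),
        "centroid_size": aligned.centroid_sizes,
        "dfa_score": result.scores,
    })
    return {"aligned": aligned, "dfa": result, "scores": scores}


def run_study(cfg: ScenarioConfig,
              n_permutations: int = 999,
              n_boot: int = 2000,
              h2: float = pstfst.DEFAULT_H2,
              seed: Optional[int] = None,
              outdir=None) -> Dict:
    """Run the complete analysis on data generated from ``cfg``.

    ``seed`` (defaults to ``cfg.seed``) drives the analysis-side randomness
    (permutation tests, bootstraps); data generation is driven by
    ``cfg.seed``.
    """
    seed = cfg.seed if seed is None else seed
    data = generate_all(cfg, outdir=outdir)
    specimens = data["specimens"]
    results: Dict[str, object] = {}

    # --- habitat use across lakes ---
    env_fit = models.abundance_model(data["environment"])
    results["environment"] = {"fit": env_fit}

    # --- morphometrics ---
    body = morphometrics_stage(data["body"], specimens,
                               n_permutations=n_permutations, seed=seed)
    chela = morphometrics_stage(data["chela"], specimens,
                                n_permutations=n_permutations, seed=seed + 1)
    size_lmm = models.trait_lmm(
        specimens.rename(columns={"carapace_length": "cl"}), "cl",
        with_interaction=False)
    body_lmm = models.trait_lmm(body["scores"], "dfa_score")
    chela_lmm = models.trait_lmm(chela["scores"], "dfa_score")
    results["morphometrics"] = {
        "body": body, "chela": chela,
        "size_lmm": size_lmm, "body_lmm": body_lmm, "chela_lmm": chela_lmm,
        "sex_ratio": models.sex_ratio_test(specimens),
    }

    # --- trophic metrics ---
    metrics = trophic_metrics(data["isotopes"])
    tp_lmm = models.trait_lmm(metrics, "TP", with_interaction=False,
                              predictors=("habitat",))
    lr_fit = models.lr_glmm(metrics)
    shape_scores = (body["scores"][["specimen_id", "dfa_score"]]
                    .rename(columns={"dfa_score": "body_dfa"})
                    .merge(chela["scores"][["specimen_id", "dfa_score"]]
                           .rename(columns={"dfa_score": "chela_dfa"}),
                           on="specimen_id"))
    joined = metrics.merge(shape_scores, left_on="sample_id",
                           right_on="specimen_id")
    lr_shape = models.lr_on_shape(joined)
    results["trophic"] = {"metrics": metrics, "tp_lmm": tp_lmm,
                          "lr_glmm": lr_fit, "lr_on_shape": lr_shape}

    # --- population genetics ---
    div = diversity(data["genotypes"])
    fst = wc_fst(data["genotypes"], grouping="habitat_paired",
                 n_boot=n_boot, seed=seed)
    results["popgen"] = {"diversity": div, "fst": fst}

    # --- P_ST vs F_ST ---
    traits = {
        "body_dfa": (body["scores"]["dfa_score"].to_numpy(),
                     body["scores"]["habitat"].to_numpy()),
        "chela_dfa": (chela["scores"]["dfa_score"].to_numpy(),
                      chela["scores"]["habitat"].to_numpy()),
        "trophic_position": (metrics["TP"].to_numpy(),
                             metrics["habitat"].to_numpy()),
        "littoral_reliance_sqrt": (np.sqrt(metrics["LR_clamped"].to_numpy()),
                                   metrics["habitat"].to_numpy()),
    }
    fst_ci = fst.ci95
    pst_results = {}
    verdicts = {}
    for i, (trait, (values, habitat)) in enumerate(traits.items()):
        est = pstfst.pst_estimate(values, habitat, trait, h2=h2,
                                  n_boot=n_boot, seed=seed + 10 + i)
        pst_results[trait] = est
        verdicts[trait] = pstfst.classify(est.ci95, fst_ci, trait=trait)
    results["pst_fst"] = {"pst": pst_results, "fst": fst, "verdicts": verdicts}
    return results


def summarize(results: Dict) -> Dict[str, float]:
    """Flatten a study-results dict into the headline numbers."""
    body = results["morphometrics"]["body"]["dfa"]
    chela = results["morphometrics"]["chela"]["dfa"]
    fst = results["pst_fst"]["fst"]
    pst = results["pst_fst"]["pst"]
    verdicts = results["pst_fst"]["verdicts"]
    metrics = results["trophic"]["metrics"]
    tp_means = metrics.groupby("habitat")["TP"].mean()
    glmm = results["trophic"]["lr_glmm"]
    preds = glmm.diagnostics["predicted_means"]
    div_means = results["popgen"]["diversity"].attrs["pop_means"]
    out = {
        "body_t_square": body.t_square,
        "body_dfa_p": body.p_value,
        "chela_t_square": chela.t_square,
        "chela_dfa_p": chela.p_value,
        "fst_global": fst.theta_reported,
        "fst_ci_low": max(0.0, fst.ci95[0]),
        "fst_ci_high": max(0.0, fst.ci95[1]),
        "tp_littoral_mean": float(tp_means["littoral"]),
        "tp_pelagic_mean": float(tp_means["pelagic"]),
        "lr_littoral_mean": float(preds["littoral"]["mean"]),
        "lr_pelagic_mean": float(preds["pelagic"]["mean"]),
        "he_mean": float(div_means["He"].mean()),
        "ar_mean": float(div_means["A_R"].mean()),
    }
    for trait in TRAITS:
        out[f"pst_{trait}"] = pst[trait].pst
        out[f"pst_{trait}_ci_low"] = pst[trait].ci95[0]
        out[f"pst_{trait}_ci_high"] = pst[trait].ci95[1]
        out[f"verdict_{trait}"] = verdicts[trait].relation
    return out
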