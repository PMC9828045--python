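"""End-to-end study workflow: alignment, modularity testing, trait models.

The pipeline executes the stages in analysis order — GPA and symmetry
decomposition, the phylogenetic allometry gate, CR permutation tests (raw
and phylogenetically corrected), likelihood model selection over the
hypothesis ledger, within/between-module integration estimates, then
per-module evolutionary model fitting, rate comparison and disparity for
the winning hypothesis — and collects every result, along with seeds and
a config hash, into a JSON-serializable report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from morphomod import io as mio
from morphomod.hypotheses import enumerate_schemes
from morphomod.modularity import (
    cr_permutation_test,
    compare_cr,
    landmark_correlations,
    emmli_fit,
    integration_report,
)
from morphomod.phylo import Phylogeny
from morphomod.procrustes import symmetry_decompose, phylo_allometry_test
from morphomod.trait_models import (
    model_support_over_trees,
    multi_module_rates,
    module_disparity,
    phylo_half_life,
    MODEL_ORDER,
)


@dataclass
class PipelineConfig:
    landmarks: str
    tree: str  # Newick file; may contain multiple trees for model-support averaging
    ledger: str
    pairing: str
    output_dir: str
    n_perm: int = 999
    n_sim: int = 999
    n_trees: int = 100
    seed: int = 0
    allometry_correction: bool = False
    best_hypothesis_override: Optional[str] = None
    models: tuple = MODEL_ORDER

    def validate(self) -> None:
        for name in ("landmarks", "tree", "ledger", "pairing"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.n_perm < 99:
            raise ValueError("n_perm must be at least 99")

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # where results land does not affect them
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _read_trees(path: str | Path, limit: int) -> list[Phylogeny]:
    text = Path(path).read_text()
    chunks = [c.strip() + ";" for c in text.split(";") if c.strip()]
    return [Phylogeny.from_newick(c) for c in chunks[:limit]]


def run_study(config: PipelineConfig) -> dict:
    """Run the full workflow and return (and write) the study report."""
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2 ** 31)) for name in ("allometry", "cr", "cr_phylo", "rates")}

    dataset = mio.read_landmarks(config.landmarks)
    trees = _read_trees(config.tree, config.n_trees)
    tree = trees[0]
    pairing = mio.read_symmetry_pairing(config.pairing)
    ledger = mio.read_hypothesis_ledger(config.ledger, dataset.landmark_labels)
    tree.check_tips(dataset.specimen_labels)

    report: dict = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_perm": config.n_perm,
            "n_trees": len(trees),
        }
    }

    # stage 1: superimposition and symmetry decomposition
    shapes = symmetry_decompose(dataset, pairing)

    # stage 2: allometry gate (size correction is opt-in and off by default)
    allom = phylo_allometry_test(shapes, tree, n_perm=config.n_perm, seed=seeds["allometry"])
    report["allometry"] = {
        "effect_fraction": allom.effect_fraction,
        "p_value": allom.p_value,
        "n_permutations": allom.n_permutations,
        "correction_applied": bool(config.allometry_correction),
    }
    if config.allometry_correction and allom.p_value < 0.05:
        # residualize shape on log centroid size (ordinary least squares on
        # the symmetric component), keeping the mean shape
        X = shapes.flat()
        x = np.log(shapes.centroid_sizes)
        A = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(A, X, rcond=None)
        resid = X - A @ beta + X.mean(axis=0, keepdims=True)
        shapes.symmetric = resid.reshape(shapes.symmetric.shape)
        shapes.symmetric -= shapes.symmetric.mean(axis=1, keepdims=True)

    # stage 3: CR permutation tests, raw and phylogenetically corrected
    cr_rows = []
    cr_raw, cr_phylo = [], []
    for part in ledger:
        raw = cr_permutation_test(shapes, part, n_perm=config.n_perm, seed=seeds["cr"])
        cor = cr_permutation_test(shapes, part, n_perm=config.n_perm, seed=seeds["cr_phylo"], tree=tree)
        cr_raw.append(raw)
        cr_phylo.append(cor)
        cr_rows.append({
            "hypothesis": part.name, "category": part.category,
            "cr": raw.cr, "p": raw.p_value,
            "z_cr": raw.z_cr if raw.p_value < 0.05 else None,
            "cr_corrected": cor.cr, "p_corrected": cor.p_value,
            "z_cr_corrected": cor.z_cr if cor.p_value < 0.05 else None,
        })
    report["cr_tests"] = cr_rows
    report["cr_ranking"] = compare_cr(cr_raw).to_dict(orient="records")

    # stage 4: likelihood model selection over parameterization schemes
    schemes = enumerate_schemes(ledger, dataset.landmark_labels)
    corr_raw = landmark_correlations(shapes)
    corr_phylo = landmark_correlations(shapes, tree=tree)
    fits_raw = emmli_fit(corr_raw, schemes)
    fits_phylo = emmli_fit(corr_phylo, schemes)
    report["emmli"] = [
        {"scheme": f.scheme_id, "max_l": f.max_l, "k": f.k, "aicc": f.aicc,
         "delta_aicc": f.delta_aicc, "weight": f.weight}
        for f in fits_raw
    ]
    report["emmli_corrected"] = [
        {"scheme": f.scheme_id, "max_l": f.max_l, "k": f.k, "aicc": f.aicc,
         "delta_aicc": f.delta_aicc, "weight": f.weight}
        for f in fits_phylo
    ]
    best_fit = fits_raw[0]
    best_name = best_fit.scheme_id.rsplit("-", 1)[0] if best_fit.scheme_id != "null" else None
    report["best_scheme"] = best_fit.scheme_id

    corrected_same = next((f for f in fits_phylo if f.scheme_id == best_fit.scheme_id), None)
    report["integration"] = integration_report(best_fit, corrected_same).to_dict(orient="records")

    # stage 5-6: trait models, rates, disparity on the winning hypothesis
    chosen_name = config.best_hypothesis_override or best_name
    if chosen_name is None:
        report["trait_models"] = None
        report["note"] = "null model won: no modules to fit"
    else:
        part = next(p for p in ledger if p.name == chosen_name)
        report["chosen_hypothesis"] = chosen_name
        idx = part.module_indices(dataset.landmark_labels)
        X = shapes.flat()
        module_results = {}
        for mod, lms in idx.items():
            cols = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in lms])
            support = model_support_over_trees(
                X[:, cols], trees, models=config.models, order=shapes.specimen_labels
            )
            winner = max(support.models, key=lambda m: (support.percent_preferred[m],
                                                        -MODEL_ORDER.index(m)))
            entry = {
                "mean_gic": support.mean_gic, "sd2_gic": support.sd2_gic,
                "percent_preferred": support.percent_preferred,
                "n_trees": support.n_trees, "best_model": winner,
                "mean_parameter": support.mean_parameter,
            }
            if winner == "OU" and support.mean_parameter["OU"] > 0:
                entry["t_half_myr"] = phylo_half_life(support.mean_parameter["OU"], tree.height)
            module_results[mod] = entry
        report["trait_models"] = module_results

        rates = multi_module_rates(shapes, part, tree, n_sim=config.n_sim, seed=seeds["rates"])
        report["rates"] = {
            "sigma2_mult": rates.rates,
            "observed_ratio": rates.observed_ratio,
            "p_value": rates.p_value,
            "pairwise_p": rates.pairwise_p.to_dict(),
        }
        disp = module_disparity(shapes, part)
        report["disparity"] = {
            "procrustes_variance": disp.disparities,
            "pairwise_p": disp.pairwise_p.to_dict(),
        }

    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    import pandas as pd

    pd.DataFrame(report["cr_tests"]).to_csv(out_dir / "cr_tests.tsv", sep="\t", index=False)
    pd.DataFrame(report["emmli"]).to_csv(out_dir / "emmli.tsv", sep="\t", index=False)
    if report.get("integration"):
        pd.DataFrame(report["integration"]).to_csv(out_dir / "integration.tsv", sep="\t", index=False)
    if report.get("trait_models"):
        rows = []
        for mod, entry in report["trait_models"].items():
            for m in entry["mean_gic"]:
                rows.append({
                    "module": mod, "model": m, "mean_gic": entry["mean_gic"][m],
                    "sd2_gic": entry["sd2_gic"][m],
                    "percent_preferred": entry["percent_preferred"][m],
                    "best": m == entry["best_model"],
                })
        pd.DataFrame(rows).to_csv(out_dir / "trait_models.tsv", sep="\t", index=False)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
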