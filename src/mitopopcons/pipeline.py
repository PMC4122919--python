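"""End-to-end orchestration: simulate -> bias-correct -> correlate -> HMM -> evaluate.

One config (YAML or in-memory) drives all stages with explicit seeds; a
rerun with the same config and seed is byte-identical for every output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .constraint_stats import (
    CorrelationResult,
    classify_sites,
    maf_divergence_correlation,
    per_gene_correlations,
    spearman,
    window_average,
)
from .core_io import write_elements
from .evaluation import (
    DEFAULT_SIZE_GRID,
    element_recovery,
    permutation_overlap_test,
    power_curve,
    summarize_elements,
    threshold_elements,
)
from .mutbias import ReplicationModel, dssh_track, fit_poisson_glm, residual_partial_correlation
from .popcons_hmm import baum_welch_train, call_elements, default_transition, viterbi_decode
from .synthetic_data import (
    SyntheticConfig,
    emit_dataset,
    generate_layout,
    simulate_divergence,
    simulate_site_alleles,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Per-stage configuration with the analysis defaults baked in.

    Defaults mirror the reference protocol: 10 Baum–Welch restarts, 10,000
    overlap permutations, 10-bp adjacent correlation windows, power-analysis
    sample sizes 100..1800 by 100 plus 1,864.
    """

    seed: int = 0
    simulate: SyntheticConfig = field(default_factory=SyntheticConfig)
    hmm_stay_probability: float = 0.99
    hmm_restarts: int = 10
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    window_width: int = 10
    window_step: int = 10
    overlap_permutations: int = 10000
    overlap_scheme: str = "independent_uniform_circular"
    divergence_element_threshold: float = 0.5
    power_enabled: bool = False
    power_sizes: tuple = DEFAULT_SIZE_GRID
    power_replicates: int = 3

    def __post_init__(self) -> None:
        if isinstance(self.simulate, dict):
            self.simulate = SyntheticConfig.from_dict(self.simulate)
        # one master seed propagates into the simulation block
        self.simulate.seed = self.seed

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        payload = asdict(self)
        payload["power_sizes"] = list(self.power_sizes)
        return payload


def _corr(res: CorrelationResult) -> dict:
    return {
        "rho": res.rho,
        "p": res.p_value,
        "p_reported": res.p_reported,
        "n": res.n,
    }


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage on one synthetic dataset and write a report bundle.

    Returns the report dict; files written under ``out_dir``: the dataset
    (core_io formats), called element BEDs, the per-gene correlation TSV,
    ``report.json`` and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}

    # --- stage 1: simulate -------------------------------------------------
    sim = config.simulate
    dataset_paths = emit_dataset(sim, out / "dataset")
    annotations, truth = generate_layout(sim)
    sites = simulate_site_alleles(sim, truth, seed=sim.seed + 1)
    neg_track, prob_track = simulate_divergence(sim, truth, seed=sim.seed + 2)
    L = sim.genome_length
    report["simulate"] = {
        "genome_length": L,
        "n_samples": sim.n_samples,
        "n_genes": len({r.name for r in annotations.records}),
        "polymorphic_fraction": float((sites.allele_count > 1).mean()),
        "mean_alleles_per_site": float(sites.allele_count.mean()),
        "truth_elements": len(truth.elements),
        "truth_bp": truth.elements.total_bp,
        "dataset_files": {k: Path(v).name for k, v in dataset_paths.items()},
    }

    # --- stage 2: mutational-bias correction -------------------------------
    control = [(r.start, r.end) for r in annotations.by_class("control")]
    model = ReplicationModel(
        L, sim.origin_h % L, sim.origin_l % L, sim.leading_direction, control_region=control
    )
    dssh = dssh_track(model)
    neg = neg_track.values.copy()
    neg[neg_track.missing] = np.nan
    usable = np.isfinite(dssh) & np.isfinite(neg)
    fit = fit_poisson_glm(sites.allele_count[usable], dssh[usable])
    residuals = np.full(L, np.nan)
    residuals[usable] = fit.residuals
    corrected = residual_partial_correlation(fit, neg[usable])
    dssh_divergence = spearman(dssh[usable], neg[usable])
    report["mutational_bias"] = {
        "glm": {
            "intercept": fit.intercept,
            "slope": fit.slope,
            "deviance": fit.deviance,
            "iterations": fit.iterations,
            "residual_type": fit.residual_type,
        },
        "n_sites_analyzed": int(usable.sum()),
        "dssh_divergence_correlation": _corr(dssh_divergence),
        "corrected_site_correlation": _corr(corrected),
    }

    # --- stage 3: correlation analyses -------------------------------------
    ok = np.isfinite(neg)
    site_corr = spearman(sites.allele_count[ok].astype(float), neg[ok])
    poly_win = window_average(
        sites.allele_count.astype(float), config.window_width, config.window_step
    )
    div_win = window_average(neg, config.window_width, config.window_step)
    wok = np.isfinite(poly_win) & np.isfinite(div_win)
    window_corr = spearman(poly_win[wok], div_win[wok])
    gene_table, tally = per_gene_correlations(
        sites, neg_track, annotations, residuals=residuals
    )
    gene_table.to_csv(out / "per_gene_correlations.tsv", sep="\t", index=False)
    mask = classify_sites(annotations, truth.sequence)
    class_corrs = {}
    for label in ("second_codon_position", "fourfold_degenerate", "rna_gene",
                  "noncoding_control", "noncoding_other"):
        idx = mask.positions(label)
        idx = idx[np.isfinite(neg[idx])]
        if idx.size >= 3 and np.ptp(sites.allele_count[idx]) > 0 and np.ptp(neg[idx]) > 0:
            class_corrs[label] = _corr(spearman(sites.allele_count[idx].astype(float), neg[idx]))
        else:
            class_corrs[label] = None
    maf_corr = maf_divergence_correlation(sites, neg_track)
    report["correlations"] = {
        "site_level": _corr(site_corr),
        "windowed": {**_corr(window_corr), "width": config.window_width,
                     "step": config.window_step},
        "per_gene_significance": tally,
        "site_class": class_corrs,
        "maf_divergence": _corr(maf_corr),
    }

    # --- stage 4: HMM element calling --------------------------------------
    transition = default_transition(config.hmm_stay_probability)
    train = baum_welch_train(
        sites.allele_count,
        fixed_transition=transition,
        n_restarts=config.hmm_restarts,
        seed=config.seed + 10,
        tol=config.hmm_tol,
        max_iter=config.hmm_max_iter,
    )
    path = viterbi_decode(train.params, sites.allele_count)
    elements = call_elements(path, train.functional_state, L)
    write_elements(elements, out / "mitopopcons_elements.bed")
    train.params.to_json(out / "hmm_params.json")
    report["hmm"] = {
        "log_likelihood": train.log_likelihood,
        "restart_log_likelihoods": train.restart_log_likelihoods,
        "functional_state": train.functional_state,
        "emission": train.params.emission.tolist(),
        "n_elements": len(elements),
        "mean_element_length_bp": elements.mean_length,
    }

    # --- stage 5: evaluation ------------------------------------------------
    divergence_elements = threshold_elements(
        prob_track, config.divergence_element_threshold
    )
    write_elements(divergence_elements, out / "divergence_elements.bed")
    overlap = permutation_overlap_test(
        elements,
        divergence_elements,
        n_perm=config.overlap_permutations,
        scheme=config.overlap_scheme,
        seed=config.seed + 20,
    )
    evaluation = {
        "overlap_bp": overlap.observed_bp,
        "overlap_p": overlap.p_value,
        "overlap_p_report": overlap.p_report,
        "n_permutations": overlap.n_permutations,
        "mitopopcons_summary": summarize_elements(elements, annotations),
        "divergence_summary": summarize_elements(divergence_elements, annotations),
        "truth_recovery": element_recovery(elements, truth.elements),
    }
    if config.power_enabled:
        curve = power_curve(
            sites,
            truth.elements,
            sizes=config.power_sizes,
            hmm_config={
                "fixed_transition": transition,
                "n_restarts": config.hmm_restarts,
                "tol": config.hmm_tol,
                "max_iter": config.hmm_max_iter,
            },
            seed=config.seed + 30,
            replicates=config.power_replicates,
        )
        log_corr = spearman(curve.power, np.log(curve.sizes.astype(float)))
        evaluation["power_curve"] = {
            "sizes": curve.sizes.tolist(),
            "power": curve.power.tolist(),
            "precision": curve.precision.tolist(),
            "f1": curve.f1.tolist(),
            "metric": curve.metric,
            "replicates": curve.replicates,
            "spearman_power_vs_log_size": _corr(log_corr),
        }
    report["evaluation"] = evaluation

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.simulate.digest(),
        "version": __version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return report
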