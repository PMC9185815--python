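"""End-to-end orchestration: simulate -> filter -> univariate -> diversity ->
train (both variants) -> CA19-9 fusion -> calibrate -> external evaluation.

`RunConfig` is a flat record (loadable from YAML) naming the inputs, the
thresholds of every stage and one master seed; `run_pipeline` runs all stages
and writes TSV/JSON artifacts plus a manifest, and rerunning with an
identical config reproduces every numeric output exactly.  The numbered
scripts under ``analysis/`` are thin drivers over the same functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import make_cv_scheme, roc_evaluate, train_ensemble
from .diversity import bray_curtis, hill_diversity, permanova
from .fusion import (calibrate_threshold, combine_and, combine_or,
                     encode_ca199, evaluate_external)
from .profiles import (filter_model_features, filter_taxa, to_counts,
                       write_metadata_tsv, write_profile_tsv)
from .synthetic import (SyntheticSpec, generate_cohort, generate_external_panel,
                        simulate_ca199)
from .univariate import wilcoxon_screen

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_EXTERNAL_PANEL"]

#: four other-disease cohorts sharing only the depletion signature, plus a
#: healthy cohort — the cross-disease specificity panel
DEFAULT_EXTERNAL_PANEL = (
    ("crohns", "other_disease", 40, 11),
    ("cirrhosis", "other_disease", 40, 12),
    ("t2d", "other_disease", 40, 13),
    ("ibs", "other_disease", 40, 14),
    ("healthy_ext", "healthy", 40, 15),
)


@dataclass
class RunConfig:
    outdir: str = "results/run"
    seed: int = 42
    # filtering
    min_abund: float = 1e-5
    min_prev_frac: float = 0.02
    model_abund_cutoff: float = 0.001
    # normalization / modelling
    pseudocount: float = 1e-5
    n_repeats: int = 10
    n_folds: int = 10
    target_specificity: float = 0.90
    ca199_threshold: float = 37.0
    ca199_missing_frac: float = 0.0
    # diversity
    diversity_n_iter: int = 25
    permanova_n_perm: int = 999
    # synthetic cohort block (None fields fall back to SyntheticSpec defaults)
    synthetic: dict = field(default_factory=dict)
    external_panel: tuple = DEFAULT_EXTERNAL_PANEL

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "external_panel" in raw:
            raw["external_panel"] = tuple(tuple(c) for c in raw["external_panel"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the scientific configuration; output location excluded."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        enc = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> list[str]:
    return [f"seed={cfg.seed}", f"config_hash={cfg.config_hash()}"]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full synthetic train-and-evaluate workflow; returns the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(cfg)

    spec = SyntheticSpec(**{**cfg.synthetic, "seed": cfg.seed})
    cohort = generate_cohort(spec)
    write_profile_tsv(cohort.profile, out / "profile_raw.tsv", comments=hdr)
    (out / "truth.json").write_text(json.dumps(cohort.truth))

    is_case = (cohort.metadata["group"] == "PDAC").to_numpy()
    ca = simulate_ca199(pd.Series(is_case, index=cohort.metadata.index),
                        spec.ca199_sensitivity, spec.ca199_specificity,
                        cfg.ca199_missing_frac, seed=cfg.seed + 7)
    meta = cohort.metadata.assign(ca199_level=ca["level"], ca199_code=ca["code"])
    write_metadata_tsv(meta, out / "metadata.tsv", comments=hdr)

    filtered = filter_taxa(cohort.profile, cfg.min_abund, cfg.min_prev_frac)
    model_table = filter_model_features(filtered, cfg.model_abund_cutoff)
    write_profile_tsv(model_table, out / "profile_model.tsv", comments=hdr)

    uni = wilcoxon_screen(model_table, is_case)
    uni.to_csv(out / "univariate.tsv", sep="\t", index=False)

    counts = to_counts(cohort.profile, meta["depth"])
    alpha = pd.concat(
        [hill_diversity(counts, q, n_iter=cfg.diversity_n_iter, seed=cfg.seed + q)
         for q in (0, 1, 2)],
        ignore_index=True,
    )
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", index=False)
    bc = bray_curtis(cohort.profile)
    perma = permanova(bc, meta["group"], n_perm=cfg.permanova_n_perm, seed=cfg.seed + 3)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")

    scheme = make_cv_scheme(is_case, cfg.n_repeats, cfg.n_folds, True, cfg.seed,
                            tuple(map(str, model_table.columns)))
    ensembles, rocs = {}, {}
    for variant in ("unconstrained", "enrichment_constrained"):
        ens = train_ensemble(model_table, is_case, scheme, variant,
                             pseudocount=cfg.pseudocount)
        ens.to_json(out / f"model_{variant}.json")
        ensembles[variant] = ens
        rocs[variant] = roc_evaluate(ens.cv_scores.to_numpy(), is_case)

    codes = encode_ca199(meta["ca199_level"], cfg.ca199_threshold)
    fusion_rows = []
    for variant, ens in ensembles.items():
        for combo, fn in (("or", combine_or), ("and", combine_and)):
            fused = fn(ens.cv_scores, codes)
            roc = roc_evaluate(fused.to_numpy(), is_case)
            fusion_rows.append({"model_variant": variant, "combination": combo,
                                "auroc": roc.auroc, "ci_low": roc.ci95[0],
                                "ci_high": roc.ci95[1]})
    pd.DataFrame(fusion_rows).to_csv(out / "fusion_auroc.tsv", sep="\t", index=False)

    panel = generate_external_panel(spec, list(cfg.external_panel))
    external_rows = []
    for variant, ens in ensembles.items():
        # calibrate on the controls' out-of-fold CV scores: held-out scores are
        # the unbiased stand-in for how fresh control samples will score
        ctrl_scores = ens.cv_scores.loc[~is_case]
        calib = calibrate_threshold(ctrl_scores.to_numpy(), cfg.target_specificity)
        for c in panel:
            external_rows.append(evaluate_external(ens, calib, c.profile, c.metadata))
    external = pd.concat(external_rows, ignore_index=True)
    external.to_csv(out / "external_eval.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": dataclasses.asdict(cfg),
        "versions": {"python": platform.python_version(), "pdacmicro": __version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "n_features_raw": int(cohort.profile.shape[0]),
        "n_features_model": int(model_table.shape[0]),
        "n_samples": int(cohort.profile.shape[1]),
        "permanova": {"R2": perma.R2, "F": perma.F, "p": perma.p},
        "auroc": {v: rocs[v].auroc for v in rocs},
        "auroc_ci": {v: list(rocs[v].ci95) for v in rocs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
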