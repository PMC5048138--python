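"""One-command orchestration: build -> balance -> encode -> rank -> evaluate.

A :class:`PipelineConfig` (loadable from YAML) fully determines a run;
every artifact lands in the run directory together with the resolved
config and its hash, so re-running the same config reproduces every
number.  Stages whose artifact already exists under a matching config
hash are skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataset as ds
from . import encoding as enc
from . import evaluate as ev
from . import profiles as pf
from . import readwrite as rw
from . import selection as sel
from . import simulate as sim
from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated, serializable description of one full run."""

    # inputs: either file paths ...
    fasta: str | None = None
    annotations: str | None = None
    sites: str | None = None
    # ... or a synthetic preset
    simulate_preset: str | None = None  # "paper" | "small" | None
    simulate_signal: str = "strong"

    seed: int = 1
    balance_k: int = 100
    windows: dict = field(
        default_factory=lambda: {"w1": 12, "w2": 12, "w3": 24, "w4": 18}
    )
    sweep_windows: bool = False
    sweep_sizes: list[int] = field(default_factory=lambda: list(range(10, 31, 2)))
    pwm_p0: float = 0.05
    pwm_alpha: float = 1.0
    svm_C: float = 1.0
    svm_gamma: float | None = None
    grid_search: bool = False
    run_ifs: bool = True
    jackknife_pwm_per_fold: bool = True

    def __post_init__(self) -> None:
        has_files = self.fasta and self.annotations and self.sites
        if not has_files and self.simulate_preset is None:
            raise ParameterError(
                "config must give fasta+annotations+sites or a simulate preset"
            )
        if self.simulate_preset not in (None, "paper", "small"):
            raise ParameterError(f"unknown preset {self.simulate_preset!r}")
        enc.WindowConfig(**self.windows)  # validates sizes
        if self.balance_k < 1:
            raise ParameterError("balance_k must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def window_config(self) -> enc.WindowConfig:
        return enc.WindowConfig(**self.windows)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate_preset:
        params = (
            sim.paper_scale_preset(config.seed)
            if config.simulate_preset == "paper"
            else sim.small_preset(config.seed)
        )
        params = sim.GeneratorParams(
            **{**params.__dict__, "signal": config.simulate_signal}
        )
        proteins, sites = sim.generate(params)
        sim.write_outputs(proteins, sites, outdir / "inputs")
        return proteins, sites
    proteins = rw.read_fasta(config.fasta)
    proteins = rw.read_annotations(config.annotations, proteins)
    sites = rw.read_site_table(config.sites, proteins)
    return proteins, sites


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage; returns a summary dict (also saved as JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    hash_file = outdir / "config_hash.txt"
    cached = hash_file.exists() and hash_file.read_text().strip() == digest
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    hash_file.write_text(digest + "\n")

    summary_path = outdir / "summary.json"
    if cached and summary_path.exists():
        log.info("config hash %s unchanged; reusing %s", digest, summary_path)
        return json.loads(summary_path.read_text())

    table = enc.PropertyTable.load()

    log.info("stage build: loading inputs")
    proteins, sites = _load_inputs(config, outdir)
    positives, negatives = ds.build_dataset(proteins, sites)
    log.info("built %d positive / %d negative windows", len(positives), len(negatives))

    log.info("stage balance: k=%d per class", config.balance_k)
    wconf = config.window_config()
    pair_full = pf.PWMPair.from_windows(
        positives, negatives, p0=config.pwm_p0, alpha=config.pwm_alpha
    )
    all_max_acc = enc.dataset_max_acc(list(positives) + list(negatives))

    def encoder(ws: Sequence[ds.ResidueWindow]) -> np.ndarray:
        return enc.assemble_features(ws, wconf, pair_full, table, max_acc=all_max_acc).X

    k = min(config.balance_k, len(positives), len(negatives))
    if k < config.balance_k:
        log.warning("balance_k reduced to %d (smallest class size)", k)
    bench = ds.balance(positives, negatives, k, config.seed, encoder)
    windows = list(bench.positives) + list(bench.negatives)

    svm_config = ev.SvmConfig(C=config.svm_C, gamma=config.svm_gamma)

    if config.sweep_windows:
        log.info("stage sweep: window sizes %s", config.sweep_sizes)
        sweep_rows = []
        best_sizes = {}
        for grp in enc.GROUPS:
            bal_pair = pf.PWMPair.from_windows(
                bench.positives, bench.negatives,
                p0=config.pwm_p0, alpha=config.pwm_alpha,
            )
            best, curve = enc.optimize_window_size(
                windows, grp, config.sweep_sizes,
                evaluator=lambda X, y: ev.jackknife_auroc(X, y, svm_config),
                pwm_pair=bal_pair, table=table,
            )
            best_sizes[grp] = best
            sweep_rows += [(grp, w, a) for w, a in sorted(curve.items())]
        pd.DataFrame(sweep_rows, columns=["group", "size", "auroc"]).to_csv(
            outdir / "window_sweep.tsv", sep="\t", index=False
        )
        wconf = enc.WindowConfig(
            w1=best_sizes["F1"], w2=best_sizes["F2"],
            w3=best_sizes["F3"], w4=best_sizes["F4"],
        )
        log.info("optimal window sizes: %s", best_sizes)

    log.info("stage encode: %d features (leave-one-out F1)", wconf.n_features)
    fm = enc.assemble_features_loo(
        windows, wconf, table, p0=config.pwm_p0, alpha=config.pwm_alpha
    )
    rw.write_feature_matrix(outdir / "features.csv", fm)

    log.info("stage rank: mRMR over %d features", fm.X.shape[1])
    ranking = sel.mrmr_rank(fm.X, fm.y)
    pd.DataFrame(
        {
            "rank": np.arange(1, len(ranking.order) + 1),
            "feature_index": ranking.order,
            "feature": [fm.names[i] for i in ranking.order],
            "relevance_bits": ranking.relevance[ranking.order],
        }
    ).to_csv(outdir / "ranking.tsv", sep="\t", index=False)

    if config.grid_search:
        log.info("stage tune: grid search over C x gamma")
        svm_config, grid_rows = ev.grid_search(fm.X, fm.y, svm_config)
        pd.DataFrame(grid_rows, columns=["C", "gamma", "auroc"]).to_csv(
            outdir / "grid.tsv", sep="\t", index=False
        )

    best_k = fm.X.shape[1]
    if config.run_ifs:
        log.info("stage IFS: %d nested prefixes", fm.X.shape[1])
        curve = sel.ifs(
            fm.X, fm.y, ranking,
            evaluator=lambda X, y: ev.jackknife_auroc(X, y, svm_config),
        )
        pd.DataFrame({"k": curve.k, "auroc": curve.auroc}).to_csv(
            outdir / "ifs_curve.tsv", sep="\t", index=False
        )
        best_k = curve.best_k
        log.info("IFS peak auROC %.3f at k=%d", float(np.max(curve.auroc)), best_k)

    log.info("stage evaluate: jackknife on the final model")
    if config.jackknife_pwm_per_fold and not config.run_ifs:
        result = ev.jackknife_windows(
            bench.positives, bench.negatives, wconf, svm_config,
            table, p0=config.pwm_p0, alpha=config.pwm_alpha,
        )
        eval_k = wconf.n_features
    else:
        top = [int(i) for i in ranking.order[:best_k]]
        sub = fm.subset(top)
        result = ev.jackknife_eval(sub.X, sub.y, svm_config)
        eval_k = best_k

    with open(outdir / "eval.json", "w") as fh:
        json.dump(
            {
                "auroc": result.auroc,
                "n_features_used": eval_k,
                "C": result.config.C,
                "gamma": result.config.gamma,
                "scores": result.scores.tolist(),
                "labels": result.labels.tolist(),
                "roc": {"fpr": result.fpr.tolist(), "tpr": result.tpr.tolist()},
            },
            fh,
            indent=1,
        )

    summary = {
        "n_positive_raw": len(positives),
        "n_negative_raw": len(negatives),
        "n_per_class_balanced": k,
        "window_sizes": {
            "w1": wconf.w1, "w2": wconf.w2, "w3": wconf.w3, "w4": wconf.w4
        },
        "n_features": wconf.n_features,
        "best_k": best_k,
        "auroc": result.auroc,
        "config_hash": digest,
    }
    summary_path.write_text(json.dumps(summary, indent=1))
    log.info("done: auROC %.3f with %d features", result.auroc, eval_k)
    return summary
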