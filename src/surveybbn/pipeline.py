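"""End-to-end orchestration: generate/load -> preprocess -> discretize ->
learn the scheme x algorithm model grid -> cross-validate -> sensitivity.

A single master seed drives every stage (per-stage seeds are derived from
it), so a rerun with the same config produces byte-identical numeric
reports.  Every artifact written carries the config hash in a header line.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bbn, learn, preprocess, sensitivity as sens, validate
from .discretize import DiscreteDataset, SCHEMES, apply_scheme
from .synth import GeneratorConfig, SurveyDataset, generate_survey

log = logging.getLogger("surveybbn")


@dataclass
class PipelineConfig:
    input_path: str | None = None     # delimited table; mutually exclusive with generator
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    with_items: bool = True           # item-level columns for the reliability stage
    method: str = "equal_width"
    schemes: tuple[str, ...] = SCHEMES
    algorithms: tuple[str, ...] = learn.ALGORITHMS
    k_folds: int = 10
    target: str = "S5"
    multiplier: float = 2.0
    eps: float = 1e-6
    outdir: str = "surveybbn_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.setdefault("schemes", list(SCHEMES))
        doc["schemes"] = tuple(doc["schemes"])
        if "algorithms" in doc:
            doc["algorithms"] = tuple(doc["algorithms"])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(json.loads(json.dumps(asdict(self), default=str)),
                              sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunBundle:
    config: PipelineConfig
    reliability: preprocess.ReliabilityReport | None
    descriptives: preprocess.DescriptiveSummary
    correlations: pd.DataFrame
    models: list[learn.LearnedModel]
    validations: list[validate.ValidationReport]
    best_index: int
    sensitivity: sens.SensitivityTable
    cpt_scan: pd.DataFrame

    @property
    def best_model(self) -> learn.LearnedModel:
        return self.models[self.best_index]

    @property
    def best_validation(self) -> validate.ValidationReport:
        return self.validations[self.best_index]


def _stage_seed(master: int, stage: int) -> int:
    return int(np.random.default_rng([master, stage]).integers(2**31))


def run(config: PipelineConfig) -> RunBundle:
    """Execute every stage in order and write the artifact bundle."""
    if (config.input_path is None) == bool(config.generator is None):
        pass  # generator dict may legitimately be empty; exclusivity checked below
    if config.input_path is not None and config.generator:
        raise ValueError("set either input_path or generator settings, not both")

    stage = "load"
    try:
        if config.input_path is not None:
            sections = SurveyDataset.from_csv(config.input_path)
            items = None
        else:
            gcfg = GeneratorConfig(seed=_stage_seed(config.seed, 0),
                                   **config.generator)
            sections = generate_survey(gcfg, with_items=False)
            items = generate_survey(gcfg, with_items=True) if config.with_items else None
        if config.target not in sections.columns:
            raise ValueError(f"target {config.target!r} not among variables")

        stage = "preprocess"
        clean = preprocess.impute_mean(sections)
        rel = preprocess.reliability(preprocess.impute_mean(items)) if items else None
        desc = preprocess.describe(clean)
        corr = preprocess.correlations(clean)

        stage = "learn"
        lcfg = learn.LearnConfig(seed=_stage_seed(config.seed, 1))
        models = learn.learn_grid(clean, method=config.method,
                                  schemes=config.schemes,
                                  algorithms=config.algorithms, base_cfg=lcfg)

        stage = "validate"
        reports = []
        for model in models:
            disc = apply_scheme(clean, model.scheme, config.method, seed=lcfg.seed)
            plan = validate.make_folds(disc.n_rows, config.k_folds,
                                       disc.codes[config.target].to_numpy(),
                                       seed=_stage_seed(config.seed, 2))
            reports.append(validate.cross_validate(disc, model.network.structure,
                                                   config.target, plan))
        best = max(range(len(models)),
                   key=lambda i: (reports[i].accuracy, reports[i].auc, -i))

        stage = "sensitize"
        table = sens.influence_scan(models[best].network,
                                    multiplier=config.multiplier, eps=config.eps)
        scan = sens.cpt_sensitivity(models[best].network, config.target)
    except Exception:
        log.exception("pipeline failed in stage %s", stage)
        raise

    bundle = RunBundle(config=config, reliability=rel, descriptives=desc,
                       correlations=corr, models=models, validations=reports,
                       best_index=best, sensitivity=table, cpt_scan=scan)
    write_bundle(bundle)
    return bundle


def _write_csv(df: pd.DataFrame, path: Path, chash: str, index: bool = False) -> None:
    buf = io.StringIO()
    df.to_csv(buf, index=index, na_rep="")
    path.write_text(f"# config_hash={chash}\n" + buf.getvalue())


def write_bundle(bundle: RunBundle) -> Path:
    outdir = Path(bundle.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = bundle.config.config_hash()
    if bundle.reliability is not None:
        _write_csv(bundle.reliability.table, outdir / "reliability.csv", chash)
    _write_csv(bundle.descriptives.table, outdir / "descriptives.csv", chash)
    _write_csv(bundle.correlations, outdir / "correlations.csv", chash, index=True)
    grid = validation_grid(bundle)
    _write_csv(grid, outdir / "validation.csv", chash)
    for model in bundle.models:
        tag = f"{model.scheme}_{model.algorithm}"
        (outdir / f"model_{tag}.bif").write_text(
            f"// config_hash={chash}\n" + bbn.to_bif(model.network))
        (outdir / f"arcs_{tag}.txt").write_text(
            f"# config_hash={chash}\n" + learn.arcs_to_text(model.network.structure))
    best = bundle.best_validation
    _write_csv(best.confusion.to_frame(), outdir / "confusion_best.csv", chash,
               index=True)
    marg = marginals_table(bundle.sensitivity.baseline)
    _write_csv(marg, outdir / "marginals_best.csv", chash, index=True)
    _write_csv(bundle.sensitivity.effects, outdir / "sensitivity_best.csv", chash,
               index=True)
    _write_csv(bundle.cpt_scan, outdir / "cpt_sensitivity_best.csv", chash)
    (outdir / "run.json").write_text(json.dumps(
        {"config_hash": chash, "seed": bundle.config.seed,
         "config": json.loads(json.dumps(asdict(bundle.config), default=str)),
         "best_model": {"scheme": bundle.best_model.scheme,
                        "algorithm": bundle.best_model.algorithm},
         }, indent=2))
    (outdir / "summary.txt").write_text(f"# config_hash={chash}\n" + report(bundle))
    return outdir


def validation_grid(bundle: RunBundle) -> pd.DataFrame:
    rows = []
    for model, rep in zip(bundle.models, bundle.validations):
        rows.append({"scheme": model.scheme, "algorithm": model.algorithm,
                     "accuracy": round(rep.accuracy, 4), "auc": round(rep.auc, 4),
                     "score": round(model.score, 4)})
    return pd.DataFrame(rows)


def marginals_table(baseline: dict[str, np.ndarray]) -> pd.DataFrame:
    n_max = max(len(v) for v in baseline.values())
    rows = {}
    for node, p in baseline.items():
        pct = [round(100 * float(x), 1) for x in p]
        rows[node] = pct + [np.nan] * (n_max - len(pct))
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"C{i}" for i in range(n_max)])


def report(bundle: RunBundle) -> str:
    """Human-readable run summary mirroring the published table layouts."""
    out = []
    if bundle.reliability is not None:
        out += ["== Reliability (Cronbach alpha per section) ==",
                bundle.reliability.table.to_string(index=False), ""]
    out += ["== Descriptive summary ==",
            bundle.descriptives.table.round(3).to_string(index=False), "",
            "== Correlation matrix ==",
            bundle.correlations.round(2).to_string(), "",
            "== Model grid (accuracy / AUC per scheme x algorithm) ==",
            validation_grid(bundle).to_string(index=False), ""]
    bm = bundle.best_model
    bv = bundle.best_validation
    pct, pct_round = validate.accuracy_from_confusion(bv.confusion)
    out += [f"Best model: {bm.scheme} {bm.algorithm} "
            f"(accuracy {pct:.1f}% ~ {pct_round}%, AUC {bv.auc:.3f})", "",
            "== Confusion matrix (actual x predicted, best model) ==",
            bv.confusion.to_frame().to_string(), "",
            "== Baseline marginals (percent per state) ==",
            marginals_table(bundle.sensitivity.baseline).to_string(), "",
            "== Net-effect matrix (% change of target top state, doubling) ==",
            bundle.sensitivity.effects.round(1).to_string(), "",
            "== Influence ranking (summed |net effect|) ==",
            bundle.sensitivity.ranking.round(1).to_string(), ""]
    most = bundle.sensitivity.ranking.index[0]
    out.append(f"Most influential factor: {most}")
    return "\n".join(out) + "\n"
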