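"""End-to-end orchestration: dataset -> conformers -> fields -> PLS -> reports.

`build_model` runs one endpoint/method combination and returns everything
downstream stages need (model, predictions, validation report, AD table).
A `RunConfig` fully determines a run; its hash is stamped on the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ad as _ad
from . import conformers as _conf
from . import fields as _fields
from . import pls as _pls
from . import validation as _val
from .dataset import EndpointTable, load_pae_dataset

__all__ = ["RunConfig", "RunResult", "PipelineError", "build_model", "build_from_tables", "write_outputs"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable configuration of one modeling run."""

    endpoint: str = "LD50"
    method: str = "comfa"  # "comfa" | "comsia"
    template: str = "DMP"
    grid_spacing: float = 2.0
    grid_margin: float = 4.0
    alpha: float = 0.3
    energy_cutoff: float = 30.0
    min_sigma_comfa: float = 2.0
    min_sigma_comsia: float = 0.1
    max_components: int = 5
    seed: int = 42
    y_bound: float = 2.5
    out_dir: str = "qsar3d_run"

    def probe(self) -> _fields.ProbeSpec:
        return _fields.ProbeSpec(alpha=self.alpha, energy_cutoff=self.energy_cutoff)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land does not change the run
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: RunConfig
    model: _pls.PLSModel
    predictions: pd.DataFrame  # abbrev, role, exp, pred, res
    q2: float
    stats: dict
    contributions: dict[str, float]
    tropsha: _val.TropshaReport | None
    ad_result: _ad.ADResult
    grid: _fields.GridSpec
    index_map: list[tuple[str, int]]
    X: np.ndarray
    molecules: dict[str, _conf.Molecule3D] = field(default_factory=dict)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - annotate with stage name
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def build_descriptors(
    smiles_by_abbrev: dict[str, str],
    config: RunConfig,
    template_smiles: str | None = None,
) -> tuple[np.ndarray, list[tuple[str, int]], _fields.GridSpec, dict[str, _conf.Molecule3D]]:
    """Embed, align and featurize a set of structures in dict order."""
    spec = _conf.AlignmentSpec(template_abbrev=config.template)
    mols: dict[str, _conf.Molecule3D] = {}
    for abbrev, smi in smiles_by_abbrev.items():
        mols[abbrev] = _stage(
            "conformers", _conf.embed_and_minimize, smi, config.seed, abbrev
        )
    if config.template not in mols:
        if template_smiles is None:
            raise PipelineError(
                f"template {config.template!r} not in input set and no template SMILES given"
            )
        template = _stage(
            "conformers", _conf.embed_and_minimize, template_smiles, config.seed, config.template
        )
        aligned = {
            a: _stage("align", _conf.align_to_template, m, template, spec)[0]
            for a, m in mols.items()
        }
    else:
        aligned = _stage("align", _conf.align_ensemble, mols, spec)
    ordered = [aligned[a] for a in smiles_by_abbrev]
    grid = _stage("fields", _fields.build_grid, ordered, config.grid_spacing, config.grid_margin)
    probe = config.probe()
    if config.method == "comfa":
        blocks = list(_stage("fields", _fields.comfa_blocks, ordered, grid, probe))
        min_sigma = config.min_sigma_comfa
    elif config.method == "comsia":
        blocks = _stage("fields", _fields.comsia_blocks, ordered, grid, probe)
        min_sigma = config.min_sigma_comsia
    else:
        raise PipelineError(f"unknown method {config.method!r}")
    filtered = []
    for b in blocks:
        try:
            filtered.append(_fields.filter_columns(b, min_sigma))
        except _fields.FieldError:
            continue  # a block with no varying columns (e.g. donors) is dropped
    if not filtered:
        raise PipelineError("no descriptor columns survive filtering")
    X, index_map = _stage("fields", _fields.assemble_descriptors, filtered)
    return X, index_map, grid, aligned


def build_from_tables(
    smiles_by_abbrev: dict[str, str],
    table: EndpointTable,
    config: RunConfig,
    template_smiles: str | None = None,
) -> RunResult:
    """Run the modeling pipeline for an endpoint table + structure map."""
    order = list(table.frame["abbrev"])
    missing = [a for a in order if a not in smiles_by_abbrev]
    if missing:
        raise PipelineError(f"no structure for compounds: {missing}")
    X, index_map, grid, mols = build_descriptors(
        {a: smiles_by_abbrev[a] for a in order}, config, template_smiles
    )
    roles = np.asarray(table.frame["role"])
    y = np.asarray(table.frame["transformed_value"], dtype=float)
    train = roles == "train"
    X_train, y_train = X[train], y[train]
    n_comp = _stage("pls", _pls.select_components, X_train, y_train, config.max_components)
    q2 = _stage("pls", _pls.loo_q2, X_train, y_train, n_comp)
    model = _stage("pls", _pls.fit_pls, X_train, y_train, n_comp, index_map)
    r2, see, f_stat = _stage("pls", _pls.model_stats, model, X_train, y_train)
    model.stats["q2"] = q2
    contributions = _stage("pls", _pls.field_contributions, model, index_map)
    pred = _stage("pls", _pls.predict, model, X)
    predictions = pd.DataFrame(
        {
            "abbrev": order,
            "role": roles,
            "exp": y,
            "pred": pred,
            "res": y - pred,
        }
    )
    tropsha = None
    if (~train).sum() >= 2:
        tropsha = _stage(
            "validation",
            _val.tropsha_criteria,
            y[~train],
            pred[~train],
            float(y_train.mean()),
        )
    # AD over the combined train+test set in latent-score space
    scores_all = model.transform(X)
    lev = _stage("ad", _ad.leverage, scores_all)
    hs = _ad.h_star(model.n_components, len(order))
    ad_result = _stage(
        "ad",
        _ad.williams_classify,
        lev,
        predictions["res"].to_numpy(),
        hs,
        config.y_bound,
        order,
        model.n_components,
    )
    stats = {
        "endpoint": table.endpoint,
        "method": config.method,
        "n_components": model.n_components,
        "q2": q2,
        "r2": r2,
        "see": see,
        "f": f_stat,
        "h_star": hs,
        "config_hash": config.config_hash,
    }
    return RunResult(
        config=config,
        model=model,
        predictions=predictions,
        q2=q2,
        stats=stats,
        contributions=contributions,
        tropsha=tropsha,
        ad_result=ad_result,
        grid=grid,
        index_map=index_map,
        X=X,
        molecules=mols,
    )


def build_model(config: RunConfig) -> RunResult:
    """Run the pipeline on a packaged endpoint table."""
    ds = load_pae_dataset()
    if config.endpoint not in ds.tables:
        raise PipelineError(f"unknown endpoint {config.endpoint!r}")
    smiles = {a: rec.smiles for a, rec in ds.registry.items()}
    template_smiles = smiles.get(config.template)
    return build_from_tables(smiles, ds.tables[config.endpoint], config, template_smiles)


def write_outputs(result: RunResult, out_dir: str | Path) -> dict[str, Path]:
    """Persist a run: config, model JSON, stats/prediction/AD CSVs, SDF,
    descriptor matrix (gzip CSV) and a JSON sidecar with grid/index info."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cfg = result.config
    paths["config"] = out / "config.yaml"
    cfg.to_yaml(paths["config"])
    paths["model"] = out / "model.json"
    payload = result.model.to_dict()
    payload["config_hash"] = cfg.config_hash
    payload["grid"] = {
        "origin": list(result.grid.origin),
        "spacing": result.grid.spacing,
        "dims": list(result.grid.dims),
    }
    paths["model"].write_text(json.dumps(payload))
    stats_row = dict(result.stats)
    for kind, pct in result.contributions.items():
        stats_row[kind] = pct
    paths["stats"] = out / "stats.csv"
    pd.DataFrame([stats_row]).to_csv(paths["stats"], index=False)
    paths["predictions"] = out / "predictions.csv"
    pred = result.predictions.copy()
    pred["config_hash"] = cfg.config_hash
    pred.to_csv(paths["predictions"], index=False)
    paths["ad"] = out / "ad.csv"
    result.ad_result.to_csv(paths["ad"])
    if result.tropsha is not None:
        paths["tropsha"] = out / "tropsha.json"
        paths["tropsha"].write_text(result.tropsha.to_json())
    paths["descriptors"] = out / "descriptors.csv.gz"
    cols = [f"{kind}:{gidx}" for kind, gidx in result.index_map]
    desc = pd.DataFrame(result.X, columns=cols)
    desc.insert(0, "abbrev", list(result.predictions["abbrev"]))
    desc.to_csv(paths["descriptors"], index=False)
    paths["aligned_sdf"] = out / "aligned.sdf"
    ordered = [result.molecules[a] for a in result.predictions["abbrev"]]
    _conf.write_sdf(ordered, paths["aligned_sdf"])
    return paths
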