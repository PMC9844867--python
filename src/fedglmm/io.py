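"""File formats: encounter CSVs, and JSON for parameters, local fits,
summary statistics, fit results and partition plans.

All floating-point numbers in the exchange formats are serialized as
shortest round-trip decimal strings, so a value survives a write/read cycle
bit-exactly on any platform; the file-mediated federated workflow therefore
reproduces the in-memory iterates exactly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import federation as fed
from . import model_core as mc
from .parameters import ParamLayout, Theta
from .partitioning import PartitionPlan

log = logging.getLogger("fedglmm")

FORMAT_VERSION = "1"


def _enc(x: float) -> str:
    return repr(float(x))


def _enc_vec(v) -> list[str]:
    return [_enc(x) for x in np.asarray(v, dtype=float).ravel()]


def _dec_vec(v) -> np.ndarray:
    return np.array([float(x) for x in v], dtype=float)


def _utcnow() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat()


def _tril_pack(H: np.ndarray) -> list[str]:
    """Row-major lower triangle of a symmetric matrix."""
    p = H.shape[0]
    return [_enc(H[i, j]) for i in range(p) for j in range(i + 1)]


def _tril_unpack(vals, p: int) -> np.ndarray:
    H = np.zeros((p, p))
    it = iter(vals)
    for i in range(p):
        for j in range(i + 1):
            H[i, j] = H[j, i] = float(next(it))
    return H


# ---------------------------------------------------------------------------
# encounter tables


def read_encounters(path, spec: mc.ModelSpec, site_id: str | None = None) -> mc.SiteData:
    """Read one site's encounter CSV, enforcing the complete-case filter.

    Rows with missing values in any model column are dropped (count logged).
    Under the logit link the outcome must be coded 0/1.
    """
    path = Path(path)
    tab = pd.read_csv(path, float_precision="round_trip")
    if len(tab) == 0:
        raise mc.ModelError(f"{path}: empty file")
    required = (
        ["y", "patient_id"]
        + list(spec.common)
        + list(spec.site_specific)
        + [f.group for f in spec.factors if f.group != "patient_id"]
    )
    missing = [c for c in required if c not in tab.columns]
    if missing:
        raise mc.ModelError(f"{path}: missing required columns {missing}")
    numeric = ["y"] + list(spec.common) + list(spec.site_specific)
    for c in numeric:
        tab[c] = pd.to_numeric(tab[c], errors="raise")
    n0 = len(tab)
    tab = tab.dropna(subset=required).reset_index(drop=True)
    dropped = n0 - len(tab)
    if dropped:
        log.info("%s: complete-case filter dropped %d of %d rows", path, dropped, n0)
    if len(tab) == 0:
        raise mc.ModelError(f"{path}: no complete cases")
    if spec.link == "logit" and not tab["y"].isin([0, 1]).all():
        bad = sorted(set(tab["y"]) - {0, 1})
        raise mc.ModelError(f"{path}: logit outcome must be 0/1, found {bad}")
    if site_id is None:
        if "site_id" in tab.columns:
            ids = tab["site_id"].unique()
            if len(ids) != 1:
                raise mc.ModelError(f"{path}: multiple site_id values {ids}")
            site_id = str(ids[0])
        else:
            site_id = path.stem
    return mc.SiteData(site_id=site_id, table=tab)


def write_encounters(site: mc.SiteData, path) -> None:
    # %.17g round-trips float64 exactly, keeping file-mediated runs
    # bit-identical to in-memory ones
    site.table.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# model / run configuration


def spec_from_dict(model: dict) -> mc.ModelSpec:
    random = model.get("random", ["patient_id"])
    factors = tuple(
        mc.RandomFactor(r["group"] if isinstance(r, dict) else str(r))
        for r in random
    )
    return mc.ModelSpec(
        link=model.get("link", "logit"),
        common=tuple(model["common"]),
        site_specific=tuple(model.get("site_specific", ())),
        factors=factors,
        alpha_shared=bool(model.get("alpha_shared", False)),
        gamma_shared=bool(model.get("gamma_shared", False)),
    )


@dataclass
class RunConfig:
    """Parsed run configuration: model, algorithm controls and data sources."""

    spec: mc.ModelSpec
    algorithm: fed.FedConfig
    site_files: list[str] | None
    simulation: dict | None
    output_dir: str | None
    raw: dict

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(raw, base=path.parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        spec = spec_from_dict(raw["model"])
        alg = raw.get("algorithm", {})
        config = fed.FedConfig(
            max_iter=int(alg.get("max_iter", 5)),
            tol=float(alg.get("tol", 1e-6)),
            damping0=float(alg.get("damping0", 1e-4)),
            max_step=float(alg.get("max_step", 10.0)),
            seed=alg.get("seed"),
        )
        data = raw.get("data", {})
        site_files = data.get("sites")
        simulation = data.get("simulation")
        if (site_files is None) == (simulation is None):
            raise ValueError(
                "config must name exactly one of data.sites / data.simulation"
            )
        if site_files is not None and base is not None:
            site_files = [str((base / f)) for f in site_files]
        if site_files is not None:
            for f in site_files:
                if not Path(f).exists():
                    raise FileNotFoundError(f"site file not found: {f}")
        return cls(
            spec=spec,
            algorithm=config,
            site_files=site_files,
            simulation=simulation,
            output_dir=raw.get("output_dir"),
            raw=raw,
        )


# ---------------------------------------------------------------------------
# theta


def save_theta(theta: Theta, path, iteration: int = 0) -> None:
    layout = theta.layout
    doc = {
        "format_version": FORMAT_VERSION,
        "iteration": iteration,
        "site_ids": layout.site_ids,
        "labels": layout.labels,
        "blocks": {k: [v.start, v.stop] for k, v in layout.blocks.items()},
        "values": _enc_vec(theta.values),
        "created_utc": _utcnow(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_theta(path, spec: mc.ModelSpec):
    doc = json.loads(Path(path).read_text())
    layout = ParamLayout(spec, doc["site_ids"])
    if layout.labels != list(doc["labels"]):
        raise mc.ModelError(f"{path}: parameter labels do not match the model spec")
    return Theta(layout, _dec_vec(doc["values"])), int(doc.get("iteration", 0))


# ---------------------------------------------------------------------------
# local fits


def save_local_fit(fit: mc.LocalFit, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "site_id": fit.site_id,
        "p_beta": fit.p_beta,
        "p_alpha": fit.p_alpha,
        "t_hat": _enc_vec(fit.t_hat),
        "cov": _tril_pack(fit.cov),
        "loglik": _enc(fit.loglik),
        "converged": fit.converged,
        "grad_norm": _enc(fit.grad_norm),
        "flags": list(fit.flags),
        "created_utc": _utcnow(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_local_fit(path) -> mc.LocalFit:
    doc = json.loads(Path(path).read_text())
    t = _dec_vec(doc["t_hat"])
    return mc.LocalFit(
        site_id=doc["site_id"],
        t_hat=t,
        cov=_tril_unpack(doc["cov"], t.size),
        loglik=float(doc["loglik"]),
        converged=bool(doc["converged"]),
        grad_norm=float(doc["grad_norm"]),
        flags=tuple(doc["flags"]),
        p_beta=int(doc["p_beta"]),
        p_alpha=int(doc["p_alpha"]),
    )


# ---------------------------------------------------------------------------
# summary statistics (the federated exchange format)


def save_summary(s: fed.SummaryStats, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "site_id": s.site_id,
        "iteration": s.iteration,
        "eval_point_digest": s.eval_digest,
        "labels": list(s.labels),
        "s": _enc_vec(s.s),
        "H": _tril_pack(s.H),
        "loglik": _enc(s.loglik),
        "created_utc": _utcnow(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_summary(path) -> fed.SummaryStats:
    doc = json.loads(Path(path).read_text())
    s = _dec_vec(doc["s"])
    return fed.SummaryStats(
        site_id=doc["site_id"],
        iteration=int(doc["iteration"]),
        eval_digest=doc["eval_point_digest"],
        labels=tuple(doc["labels"]),
        s=s,
        H=_tril_unpack(doc["H"], s.size),
        loglik=float(doc["loglik"]),
    )


# ---------------------------------------------------------------------------
# fit results


def save_fit_result(result: fed.FitResult, path_json, path_table=None) -> None:
    layout = result.theta.layout
    doc = {
        "format_version": FORMAT_VERSION,
        "labels": layout.labels,
        "theta": _enc_vec(result.theta.values),
        "covariance": _tril_pack(result.covariance),
        "trace": [_enc_vec(row) for row in result.trace],
        "deltas": _enc_vec(result.deltas),
        "iterations": result.iterations,
        "converged": result.converged,
        "warnings": list(result.warnings),
        "created_utc": _utcnow(),
    }
    Path(path_json).write_text(json.dumps(doc, indent=1))
    if path_table is not None:
        se = result.std_errors
        with np.errstate(divide="ignore", invalid="ignore"):
            z = result.theta.values / se
        blocks = []
        for name, sl in layout.blocks.items():
            blocks += [name] * (sl.stop - sl.start)
        pd.DataFrame(
            {
                "term": layout.labels,
                "estimate": result.theta.values,
                "std_error": se,
                "z": z,
                "site_block": blocks,
            }
        ).to_csv(path_table, index=False)


def save_plan(plan: PartitionPlan, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "m": plan.m,
        "strategy": plan.strategy,
        "seed": plan.seed,
        "assignment": plan.assignment.tolist(),
        "counts": plan.counts.tolist(),
        "created_utc": _utcnow(),
    }
    Path(path).write_text(json.dumps(doc))


def load_plan(path) -> PartitionPlan:
    doc = json.loads(Path(path).read_text())
    return PartitionPlan(
        m=int(doc["m"]),
        assignment=np.asarray(doc["assignment"], dtype=int),
        strategy=doc["strategy"],
        seed=int(doc["seed"]),
    )


# ---------------------------------------------------------------------------
# run logs


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_log(path, command: str, seed, inputs=(), extra=None) -> None:
    """Record enough to replay a run: command, seed, input digests, version."""
    from . import __version__

    doc = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): file_digest(p) for p in inputs if Path(p).exists()},
        "created_utc": _utcnow(),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))
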