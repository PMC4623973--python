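"""Model files, sample-ledger CSV round-tripping, curve/profile tables, run logs.

Model files are YAML or JSON with top-level keys ``label``, ``temperature``,
``conformers``, ``sites``, ``couplings``; unknown keys are rejected by name.
Ledger CSVs carry a ``#``-prefixed metadata preamble (model label, seed,
schedule, canonical site order, pH ladder) followed by a plain CSV body with
columns ``replica,attempt,pH,conformer,protonation,N``, protonation rendered
as a fixed-length 0/1 string in canonical site order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .mc import SampleLedger
from .model import (
    ConformerSpec,
    CouplingTerm,
    ModelError,
    SiteSpec,
    SystemModel,
    ThermoParams,
    validate_model,
)
from .titration import TitrationCurve

__all__ = [
    "load_model",
    "save_model",
    "model_to_dict",
    "read_ledger",
    "write_ledger",
    "write_titration_curves",
    "read_titration_curves",
    "write_run_log",
]

_MODEL_KEYS = {"label", "temperature", "conformers", "sites", "couplings"}
_SITE_KEYS = {"id", "residue_class", "pKa_ref", "intrinsic_shift"}
_CONF_KEYS = {"id", "base_energy"}
_COUP_KEYS = {"site_a", "site_b", "conformer_scope", "energy"}


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ModelError(f"unknown key(s) {sorted(unknown)} in {context}")


def model_to_dict(model: SystemModel) -> dict:
    return {
        "label": model.label,
        "temperature": model.thermo.temperature,
        "conformers": [
            {"id": c.conformer_id, "base_energy": c.base_energy} for c in model.conformers
        ],
        "sites": [
            {
                "id": s.site_id,
                "residue_class": s.residue_class,
                "pKa_ref": s.pKa_ref,
                "intrinsic_shift": dict(s.intrinsic_shift),
            }
            for s in model.sites
        ],
        "couplings": [
            {
                "site_a": cp.site_a,
                "site_b": cp.site_b,
                "conformer_scope": cp.conformer_scope,
                "energy": cp.energy,
            }
            for cp in model.couplings
        ],
    }


def _model_from_dict(d: dict) -> SystemModel:
    if not isinstance(d, dict):
        raise ModelError("model file must contain a mapping at top level")
    _check_keys(d, _MODEL_KEYS, "model file")
    if "label" not in d:
        raise ModelError("model file missing required key 'label'")
    conformers = []
    for c in d.get("conformers", []):
        _check_keys(c, _CONF_KEYS, f"conformer entry {c.get('id', '?')!r}")
        conformers.append(ConformerSpec(c["id"], float(c.get("base_energy", 0.0))))
    sites = []
    for s in d.get("sites", []):
        _check_keys(s, _SITE_KEYS, f"site entry {s.get('id', '?')!r}")
        pka = s.get("pKa_ref")
        sites.append(
            SiteSpec(
                site_id=s["id"],
                residue_class=s.get("residue_class", "custom"),
                pKa_ref=None if pka is None else float(pka),
                intrinsic_shift={k: float(v) for k, v in (s.get("intrinsic_shift") or {}).items()},
            )
        )
    couplings = []
    for cp in d.get("couplings", []):
        _check_keys(cp, _COUP_KEYS, f"coupling entry {cp.get('site_a', '?')!r}")
        couplings.append(
            CouplingTerm(
                site_a=cp["site_a"],
                site_b=cp["site_b"],
                energy=float(cp["energy"]),
                conformer_scope=cp.get("conformer_scope", "all"),
            )
        )
    thermo = ThermoParams(temperature=float(d.get("temperature", 300.0)))
    return validate_model(
        SystemModel(
            label=d["label"],
            sites=tuple(sites),
            conformers=tuple(conformers),
            couplings=tuple(couplings),
            thermo=thermo,
        )
    )


def load_model(path: str | Path) -> SystemModel:
    """Load and validate a YAML or JSON model file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise ModelError(f"{path}: JSON parse error at line {e.lineno}: {e.msg}") from e
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            where = f" at line {mark.line + 1}" if mark else ""
            raise ModelError(f"{path}: YAML parse error{where}") from e
    return _model_from_dict(data)


def save_model(model: SystemModel, path: str | Path) -> None:
    """Write a model file (format chosen by extension: .json or .yaml/.yml)."""
    path = Path(path)
    d = model_to_dict(model)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# Ledger CSV

_LEDGER_COLUMNS = ["replica", "attempt", "pH", "conformer", "protonation", "N"]


def write_ledger(ledger: SampleLedger, path: str | Path) -> None:
    path = Path(path)
    meta = [
        f"# model_label: {ledger.model_label}",
        f"# seed: {ledger.seed}",
        f"# site_order: {','.join(ledger.site_order)}",
        f"# conformer_order: {','.join(ledger.conformer_order)}",
        f"# ladder: {','.join(repr(p) for p in ledger.ladder)}",
        f"# schedule: {json.dumps(ledger.schedule, sort_keys=True)}",
    ]
    df = ledger.to_dataframe()
    with path.open("w") as f:
        f.write("\n".join(meta) + "\n")
        df.to_csv(f, index=False)


def read_ledger(path: str | Path) -> SampleLedger:
    path = Path(path)
    meta: dict[str, str] = {}
    body_start = 0
    with path.open() as f:
        lines = f.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
        else:
            body_start = i
            break
    for required in ("model_label", "seed", "site_order", "conformer_order", "ladder", "schedule"):
        if required not in meta:
            raise ModelError(f"{path}: ledger missing metadata line '# {required}: ...'")
    site_order = tuple(meta["site_order"].split(","))
    conformer_order = tuple(meta["conformer_order"].split(","))
    ladder = tuple(float(p) for p in meta["ladder"].split(","))

    header = lines[body_start].strip().split(",")
    missing = [c for c in _LEDGER_COLUMNS if c not in header]
    if missing:
        raise ModelError(f"{path}: ledger missing column(s) {missing}")
    idx = {c: header.index(c) for c in _LEDGER_COLUMNS}

    n_sites = len(site_order)
    rep, att, ph, conf, mask, nprot = [], [], [], [], [], []
    ladder_set = set(ladder)
    conf_index = {c: k for k, c in enumerate(conformer_order)}
    for rownum, line in enumerate(lines[body_start + 1 :], start=body_start + 2):
        line = line.strip()
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != len(header):
            raise ModelError(f"{path}: truncated or malformed row at line {rownum}")
        proto = parts[idx["protonation"]]
        if len(proto) != n_sites or set(proto) - {"0", "1"}:
            raise ModelError(
                f"{path}: line {rownum}: protonation string {proto!r} does not match "
                f"site order of length {n_sites}"
            )
        p = float(parts[idx["pH"]])
        if p not in ladder_set:
            raise ModelError(f"{path}: line {rownum}: pH {p} not in metadata ladder")
        cname = parts[idx["conformer"]]
        if cname not in conf_index:
            raise ModelError(f"{path}: line {rownum}: unknown conformer {cname!r}")
        rep.append(int(parts[idx["replica"]]))
        att.append(int(parts[idx["attempt"]]))
        ph.append(p)
        conf.append(conf_index[cname])
        mask.append(int(proto[::-1], 2))
        nprot.append(int(parts[idx["N"]]))

    return SampleLedger(
        replica=np.array(rep, dtype=np.int32),
        attempt=np.array(att, dtype=np.int64),
        pH=np.array(ph, dtype=float),
        conformer=np.array(conf, dtype=np.int16),
        mask=np.array(mask, dtype=np.int64),
        n_protons=np.array(nprot, dtype=np.int16),
        model_label=meta["model_label"],
        site_order=site_order,
        conformer_order=conformer_order,
        ladder=ladder,
        seed=int(meta["seed"]),
        schedule=json.loads(meta["schedule"]),
    )


# ---------------------------------------------------------------------------
# Titration-curve tables


def write_titration_curves(curves: list[TitrationCurve], path: str | Path) -> None:
    """`site,pH,n_deprot,n_total,s` CSV, one block of rows per site."""
    pd.concat([c.to_dataframe() for c in curves], ignore_index=True).to_csv(path, index=False)


def read_titration_curves(path: str | Path) -> list[TitrationCurve]:
    df = pd.read_csv(path)
    missing = {"site", "pH", "s"} - set(df.columns)
    if missing:
        raise ModelError(f"{path}: titration table missing column(s) {sorted(missing)}")
    curves = []
    for sid, grp in df.groupby("site", sort=False):
        grp = grp.sort_values("pH")
        nd = grp["n_deprot"].to_numpy() if "n_deprot" in grp else None
        nt = grp["n_total"].to_numpy() if "n_total" in grp else None
        if nd is not None and np.all(nd < 0):
            nd = nt = None
        curves.append(
            TitrationCurve(
                site_id=str(sid),
                pH=grp["pH"].to_numpy(dtype=float),
                s=grp["s"].to_numpy(dtype=float),
                n_deprotonated=nd,
                n_total=nt,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Run logs


def write_run_log(path: str | Path, command: str, config: dict, seed: int | None) -> None:
    """One JSON log per command: version, seed, and a hash of the configuration."""
    blob = json.dumps(config, sort_keys=True, default=str)
    log = {
        "tool": "protolink",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str) + "\n")
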