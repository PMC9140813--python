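"""Structured-text FIS configuration and patient CSV input/output.

The configuration is a YAML document with an explicit ``format_version``,
describing every variable (universe bounds, grid resolution, terms with shape
and parameters), the rule base (clauses, connective, consequent, weight) and
the inference settings. ``load_config(save_config(system))`` reproduces an
equivalent system; decimal parameters round-trip exactly.

Patient CSVs use the header
``id,age,hb_g_dl,crp_mg_dl,plt_per_mm3,alp_u_l,group`` (``id`` and ``group``
optional). The historical aliases ``pcr`` (= CRP) and ``fa`` (= ALP, from the
Romanian *fosfatază alcalină*) are accepted in column names, as are bare
parameter names without unit suffixes. Rows with missing or non-numeric
values are rejected with their row numbers logged.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Union

import pandas as pd
import yaml

from .engine import FuzzyRule, FuzzySystem, InferenceSettings, RuleClause
from .errors import ConfigurationError, FormatError, InvalidInputError
from .membership import LinguisticVariable, MembershipFunction, Universe
from .cohorts import COLUMNS as _CANONICAL_COLUMNS
from .model import INPUT_ORDER, PatientRecord

_log = logging.getLogger(__name__)

FORMAT_VERSION = 1

#: column-name aliases, applied to the leading token of each header field
ALIASES = {"pcr": "crp", "fa": "alp"}

_DEFAULT_CONFIG = Path(__file__).parent / "data" / "default_system.yaml"

PathLike = Union[str, Path]


def default_config_path() -> Path:
    """Path of the shipped default-system configuration."""
    return _DEFAULT_CONFIG


def _variable_to_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "universe": [var.universe.lower, var.universe.upper],
        "resolution": var.universe.resolution,
        "terms": [
            {"term": t.term, "shape": t.shape, "params": list(t.params)}
            for t in var.terms
        ],
    }


def _variable_from_dict(d: dict) -> LinguisticVariable:
    try:
        name = d["name"]
        lower, upper = d["universe"]
        terms = d["terms"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed variable entry {d!r}: {exc}") from exc
    universe = Universe(name, float(lower), float(upper), int(d.get("resolution", 1001)))
    mfs = []
    for t in terms:
        try:
            mfs.append(MembershipFunction(t["term"], t["shape"], tuple(t["params"])))
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"malformed term entry {t!r} in variable {name!r}") from exc
    return LinguisticVariable(universe, tuple(mfs))


def save_config(system: FuzzySystem, path: PathLike) -> None:
    """Serialize a system to a YAML configuration file."""
    doc = {
        "format_version": FORMAT_VERSION,
        "settings": {
            "and_method": system.settings.and_method,
            "implication": system.settings.implication,
            "aggregation": system.settings.aggregation,
            "defuzzification": system.settings.defuzzification,
        },
        "inputs": [_variable_to_dict(v) for v in system.inputs],
        "output": _variable_to_dict(system.output),
        "rules": [
            {
                "if": [
                    {"var": c.variable, "term": c.term, **({"negated": True} if c.negated else {})}
                    for c in r.antecedent
                ],
                "connective": r.connective,
                "then": r.consequent_term,
                "weight": r.weight,
            }
            for r in system.rules
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False, default_flow_style=None))


def load_config(path: PathLike) -> FuzzySystem:
    """Load and fully validate a system from a YAML configuration file.

    Raises :class:`ConfigurationError` naming the offending rule or term on
    any dangling reference or out-of-range weight.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ConfigurationError(
            f"config {path}: unsupported format_version {version!r} (expected {FORMAT_VERSION})"
        )
    settings = InferenceSettings(**doc.get("settings", {}))
    inputs = tuple(_variable_from_dict(d) for d in doc.get("inputs", []))
    output = _variable_from_dict(doc["output"])
    rules = []
    for i, r in enumerate(doc.get("rules", []), start=1):
        try:
            clauses = tuple(
                RuleClause(c["var"], c["term"], bool(c.get("negated", False)))
                for c in r["if"]
            )
            rule = FuzzyRule(
                antecedent=clauses,
                consequent_term=r["then"],
                weight=float(r.get("weight", 1.0)),
                connective=r.get("connective", "and"),
            )
        except KeyError as exc:
            raise ConfigurationError(f"rule {i}: missing key {exc}") from exc
        rules.append(rule)
    # FuzzySystem.__post_init__ validates every term/variable reference.
    return FuzzySystem(inputs=inputs, output=output, rules=tuple(rules), settings=settings)


def load_default_system() -> FuzzySystem:
    """The shipped default diagnostic system, loaded from its pinned config."""
    return load_config(default_config_path())


def _canonical_column(raw: str) -> str:
    token = raw.strip().lower().split("_", 1)[0]
    return ALIASES.get(token, token)


def read_patients(path: PathLike) -> List[PatientRecord]:
    """Read patient records from CSV; invalid rows are skipped and logged."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read patient CSV {path}: {exc}") from exc

    mapping: Dict[str, str] = {}
    for col in frame.columns:
        canon = _canonical_column(str(col))
        if canon in INPUT_ORDER or canon in ("id", "group"):
            mapping.setdefault(canon, col)
    missing = [p for p in INPUT_ORDER if p not in mapping]
    if missing:
        raise FormatError(
            f"patient CSV {path} is missing required column(s) {missing}; "
            f"found header {list(frame.columns)}"
        )

    records: List[PatientRecord] = []
    for row_number, (_, row) in enumerate(frame.iterrows(), start=2):  # 1 = header line
        values = {}
        ok = True
        for param in INPUT_ORDER:
            raw = row[mapping[param]]
            try:
                value = float(raw)
            except (TypeError, ValueError):
                value = math.nan
            if not math.isfinite(value):
                _log.warning("%s row %d: non-numeric or missing %s (%r); row skipped",
                             path.name, row_number, param, raw)
                ok = False
                break
            values[param] = value
        if not ok:
            continue
        patient_id = row[mapping["id"]] if "id" in mapping else None
        if isinstance(patient_id, float) and math.isnan(patient_id):
            patient_id = None
        try:
            records.append(PatientRecord(id=patient_id, **values))
        except InvalidInputError as exc:
            _log.warning("%s row %d rejected: %s", path.name, row_number, exc)
    return records


def write_patients(records, path: PathLike) -> None:
    """Write patient records with the canonical header."""
    rows = []
    for r in records:
        row = {"id": r.id if r.id is not None else ""}
        for param in INPUT_ORDER:
            row[_CANONICAL_COLUMNS[param]] = getattr(r, param)
        rows.append(row)
    columns = ["id"] + [_CANONICAL_COLUMNS[p] for p in INPUT_ORDER]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
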