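"""Parameter objects for the splat, simple, and lun count simulators.

Each simulator has a dataclass holding its full parameter set together with a
per-field *provenance* tag recording whether the value is a shipped default,
was estimated from a real count matrix, or was set by the user.  Parameter
objects are plain data: :func:`validate_params` reports invariant violations
as values rather than raising, and :func:`update_params` returns a modified
copy, leaving its input untouched.

Configurations are serialized to YAML via :func:`write_config` /
:func:`read_config`; the round trip is exact (floats are written with their
shortest repr).
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Union

import yaml

__all__ = [
    "SplatParams",
    "SimpleParams",
    "LunParams",
    "Violation",
    "default_params",
    "validate_params",
    "update_params",
    "write_config",
    "read_config",
    "param_summary",
]

PROVENANCE_STATES = ("default", "estimated", "user")

#: Probability that the sum of group_probs may deviate from 1.
_PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class Violation:
    """A single parameter-invariant violation (data, not an exception)."""

    field: str
    reason: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}: {self.reason}"


def _default_provenance() -> dict:
    return {}


@dataclass
class _BaseParams:
    """Shared behaviour: provenance bookkeeping and field access."""

    def __post_init__(self) -> None:
        for f in self.field_names():
            self.provenance.setdefault(f, "default")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls) if f.name != "provenance"]

    def copy(self):
        return copy.deepcopy(self)

    def set_provenance(self, name: str, state: str) -> None:
        if state not in PROVENANCE_STATES:
            raise ValueError(f"unknown provenance state {state!r}")
        if name not in self.field_names():
            raise KeyError(name)
        self.provenance[name] = state


@dataclass
class SplatParams(_BaseParams):
    """Full parameter set of the splat gamma-Poisson simulation.

    The hierarchy: gene means are Gamma(``mean_shape``, rate ``mean_rate``)
    draws, optionally replaced for expression-outlier genes by the median mean
    times a LogNormal(``out_loc``, ``out_scale``) inflation factor.  Cell
    library sizes are LogNormal(``lib_loc``, ``lib_scale``).  The biological
    coefficient of variation trend is controlled by the common dispersion
    ``bcv_common`` and the inverse chi-squared degrees of freedom ``bcv_df``.
    Dropout is a logistic function of log expression with midpoint
    ``dropout_mid`` and steepness ``dropout_shape``.

    Structural parameters configure multi-group (``group_probs``, ``de_*``),
    multi-batch (``batch_cells``, ``batch_fac_*``) and differentiation-path
    (``path_*``) simulations; the ``de_*`` fields are per-group lists aligned
    with ``group_probs`` (which doubles as the per-path probability vector in
    paths mode).

    Defaults are configuration chosen to produce realistic UMI-like matrices,
    not ground truth.
    """

    n_genes: int = 10000
    n_cells: int = 100
    seed: int = 1

    mean_shape: float = 0.6
    mean_rate: float = 0.3

    lib_loc: float = 11.0
    lib_scale: float = 0.2

    out_prob: float = 0.05
    out_loc: float = 4.0
    out_scale: float = 0.5

    bcv_common: float = 0.1
    bcv_df: float = 60.0

    dropout_present: bool = False
    dropout_mid: float = 0.0
    dropout_shape: float = 1.0

    group_probs: list = field(default_factory=lambda: [1.0])
    de_prob: list = field(default_factory=lambda: [0.1])
    de_down_prob: list = field(default_factory=lambda: [0.5])
    de_loc: list = field(default_factory=lambda: [0.1])
    de_scale: list = field(default_factory=lambda: [0.4])

    batch_cells: list = field(default_factory=list)
    batch_fac_loc: float = 0.1
    batch_fac_scale: float = 0.1

    path_from: list = field(default_factory=lambda: [0])
    path_n_steps: list = field(default_factory=lambda: [100])
    path_skew: list = field(default_factory=lambda: [0.5])
    path_nonlinear_prob: float = 0.1
    path_sigma_fac: float = 0.8

    provenance: dict = field(default_factory=_default_provenance)

    def __post_init__(self) -> None:
        if not self.batch_cells:
            self.batch_cells = [self.n_cells]
        super().__post_init__()


@dataclass
class SimpleParams(_BaseParams):
    """Baseline gamma/negative-binomial simulation parameters.

    Gene means are gamma draws; counts are negative binomial around each gene
    mean with one fixed ``dispersion`` shared by all genes (default 0.1).
    """

    n_genes: int = 10000
    n_cells: int = 100
    seed: int = 1
    mean_shape: float = 0.6
    mean_rate: float = 0.3
    dispersion: float = 0.1

    provenance: dict = field(default_factory=_default_provenance)


@dataclass
class LunParams(_BaseParams):
    """Parameters for the Lun-style cell-factor negative-binomial simulation.

    Extends the simple model with a per-cell scaling factor drawn from
    Normal(``cell_factor_mean``, variance ``cell_factor_var``) and applied to
    the gene means after inverse-log2 transformation (mean times
    ``2**factor``).  Optional groups receive a fixed fold change
    ``de_fold_change`` on a ``de_prob`` fraction of genes.  Gamma shape/rate,
    dispersion and fold-change defaults are implementation defaults.
    """

    n_genes: int = 10000
    n_cells: int = 100
    seed: int = 1
    mean_shape: float = 2.0
    mean_rate: float = 2.0
    cell_factor_mean: float = 1.0
    cell_factor_var: float = 0.5
    dispersion: float = 0.1
    n_groups: int = 1
    de_prob: float = 0.1
    de_fold_change: float = 5.0

    provenance: dict = field(default_factory=_default_provenance)


_MODELS = {"splat": SplatParams, "simple": SimpleParams, "lun": LunParams}
_MODEL_NAMES = {cls: name for name, cls in _MODELS.items()}

Params = Union[SplatParams, SimpleParams, LunParams]


def model_name(p: Params) -> str:
    """Return the registry name ("splat"/"simple"/"lun") of a params object."""
    try:
        return _MODEL_NAMES[type(p)]
    except KeyError:
        raise TypeError(f"not a parameter object: {type(p).__name__}") from None


def default_params(model: str) -> Params:
    """Return a fully populated default parameter object for ``model``.

    Every field is tagged ``provenance="default"``.
    """
    try:
        cls = _MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; expected one of {sorted(_MODELS)}"
        ) from None
    return cls()


# ---------------------------------------------------------------------------
# validation


def _check_positive(p, name: str, out: list, strict: bool = True) -> None:
    v = getattr(p, name)
    if strict and not v > 0:
        out.append(Violation(name, f"must be > 0, got {v}"))
    elif not strict and v < 0:
        out.append(Violation(name, f"must be >= 0, got {v}"))


def _check_prob(out: list, name: str, v, idx: int | None = None) -> None:
    label = name if idx is None else f"{name}[{idx}]"
    if not (0.0 <= v <= 1.0):
        out.append(Violation(name, f"{label} must be in [0, 1], got {v}"))


def _validate_splat(p: SplatParams) -> list[Violation]:
    out: list[Violation] = []
    for name in ("n_genes", "n_cells"):
        if not (isinstance(getattr(p, name), (int,)) and getattr(p, name) > 0):
            out.append(Violation(name, f"must be a positive integer, got {getattr(p, name)!r}"))
    for name in ("mean_shape", "mean_rate", "bcv_df"):
        _check_positive(p, name, out, strict=True)
    for name in ("lib_scale", "out_scale", "bcv_common", "path_sigma_fac"):
        _check_positive(p, name, out, strict=False)
    _check_prob(out, "out_prob", p.out_prob)
    _check_prob(out, "path_nonlinear_prob", p.path_nonlinear_prob)

    n_groups = len(p.group_probs)
    if n_groups == 0:
        out.append(Violation("group_probs", "must contain at least one group"))
    for i, g in enumerate(p.group_probs):
        _check_prob(out, "group_probs", g, i)
    if n_groups and abs(sum(p.group_probs) - 1.0) > _PROB_SUM_TOL:
        out.append(
            Violation("group_probs", f"must sum to 1 (got {sum(p.group_probs)!r})")
        )
    for name in ("de_prob", "de_down_prob", "de_loc", "de_scale"):
        vals = getattr(p, name)
        if len(vals) != n_groups:
            out.append(
                Violation(name, f"needs one value per group ({n_groups}), got {len(vals)}")
            )
    for i, v in enumerate(p.de_prob):
        _check_prob(out, "de_prob", v, i)
    for i, v in enumerate(p.de_down_prob):
        _check_prob(out, "de_down_prob", v, i)
    for i, v in enumerate(p.de_scale):
        if v < 0:
            out.append(Violation("de_scale", f"de_scale[{i}] must be >= 0, got {v}"))

    if not p.batch_cells:
        out.append(Violation("batch_cells", "must contain at least one batch"))
    elif any((not isinstance(b, int)) or b <= 0 for b in p.batch_cells):
        out.append(Violation("batch_cells", f"entries must be positive integers, got {p.batch_cells}"))
    elif sum(p.batch_cells) != p.n_cells:
        out.append(
            Violation(
                "batch_cells",
                f"must sum to n_cells={p.n_cells}, got {sum(p.batch_cells)}",
            )
        )

    n_paths = len(p.path_from)
    for name in ("path_n_steps", "path_skew"):
        if len(getattr(p, name)) != n_paths:
            out.append(
                Violation(name, f"needs one value per path ({n_paths}), got {len(getattr(p, name))}")
            )
    for i, s in enumerate(p.path_n_steps):
        if not (isinstance(s, int) and s >= 1):
            out.append(Violation("path_n_steps", f"path_n_steps[{i}] must be an integer >= 1, got {s!r}"))
    for i, s in enumerate(p.path_skew):
        _check_prob(out, "path_skew", s, i)
    for i, origin in enumerate(p.path_from):
        if not (isinstance(origin, int) and 0 <= origin <= n_paths):
            out.append(
                Violation("path_from", f"path_from[{i}] must reference 0 (root) or a path in 1..{n_paths}, got {origin!r}")
            )
        elif origin == i + 1:
            out.append(Violation("path_from", f"path {i + 1} cannot originate from itself"))
    # cycle detection: follow origins back to the root from every path
    if not any(v.field == "path_from" for v in out):
        for i in range(n_paths):
            seen = set()
            node = i + 1
            while node != 0:
                if node in seen:
                    out.append(Violation("path_from", f"cycle involving path {node}"))
                    break
                seen.add(node)
                node = p.path_from[node - 1]
            if any(v.field == "path_from" and "cycle" in v.reason for v in out):
                break
    return out


def _validate_simple(p: SimpleParams) -> list[Violation]:
    out: list[Violation] = []
    for name in ("n_genes", "n_cells"):
        if not (isinstance(getattr(p, name), int) and getattr(p, name) > 0):
            out.append(Violation(name, f"must be a positive integer, got {getattr(p, name)!r}"))
    for name in ("mean_shape", "mean_rate", "dispersion"):
        _check_positive(p, name, out, strict=True)
    return out


def _validate_lun(p: LunParams) -> list[Violation]:
    out = _validate_simple(p)
    if p.cell_factor_var < 0:
        out.append(Violation("cell_factor_var", f"must be >= 0, got {p.cell_factor_var}"))
    if not (isinstance(p.n_groups, int) and p.n_groups >= 1):
        out.append(Violation("n_groups", f"must be a positive integer, got {p.n_groups!r}"))
    _check_prob(out, "de_prob", p.de_prob)
    if not p.de_fold_change > 0:
        out.append(Violation("de_fold_change", f"must be > 0, got {p.de_fold_change}"))
    return out


def validate_params(p: Params) -> list[Violation]:
    """Check every invariant of a parameter object.

    Returns a list of :class:`Violation` records (empty iff the object is
    valid).  Violations are data, not exceptions, so callers can report all
    problems at once.
    """
    if isinstance(p, SplatParams):
        out = _validate_splat(p)
    elif isinstance(p, LunParams):
        out = _validate_lun(p)
    elif isinstance(p, SimpleParams):
        out = _validate_simple(p)
    else:
        raise TypeError(f"not a parameter object: {type(p).__name__}")
    for name, state in p.provenance.items():
        if state not in PROVENANCE_STATES:
            out.append(Violation("provenance", f"unknown state {state!r} for field {name!r}"))
    return out


def update_params(p: Params, overrides: dict) -> Params:
    """Return a copy of ``p`` with ``overrides`` applied.

    Overridden fields are tagged ``provenance="user"``; all others keep their
    tags.  ``p`` itself is not modified.  Unknown field names raise a
    ``KeyError`` listing the valid names.
    """
    valid = p.field_names()
    unknown = [k for k in overrides if k not in valid]
    if unknown:
        raise KeyError(
            f"unknown parameter name(s) {unknown}; valid names: {valid}"
        )
    q = p.copy()
    for name, value in overrides.items():
        setattr(q, name, value)
        q.provenance[name] = "user"
    return q


# ---------------------------------------------------------------------------
# serialization


def to_dict(p: Params) -> dict:
    """Plain-python dict form of a params object, including the model name."""
    d = {"model": model_name(p)}
    for name in p.field_names():
        d[name] = copy.deepcopy(getattr(p, name))
    d["provenance"] = dict(p.provenance)
    return d


def from_dict(d: dict) -> Params:
    """Rebuild a params object from :func:`to_dict` output.

    All fields are optional; missing ones take their defaults (and keep
    provenance "default" unless the stored provenance says otherwise).
    """
    d = dict(d)
    model = d.pop("model", None)
    if model not in _MODELS:
        raise ValueError(f"config is missing a valid 'model' entry (got {model!r})")
    cls = _MODELS[model]
    provenance = d.pop("provenance", {})
    known = {f.name for f in fields(cls)} - {"provenance"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown field(s) in config: {sorted(unknown)}")
    p = cls(**d)
    p.provenance.update(provenance)
    return p


def write_config(p: Params, path) -> Path:
    """Write a params object to a YAML config file; returns the path."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(p), fh, sort_keys=False)
    return path


def read_config(path) -> Params:
    """Read a YAML config written by :func:`write_config`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return from_dict(d)


def param_summary(p: Params) -> str:
    """Human-readable listing of parameters grouped by provenance."""
    lines = [f"{model_name(p)} parameters"]
    width = max(len(n) for n in p.field_names())
    for name in p.field_names():
        tag = p.provenance.get(name, "default")
        marker = {"default": " ", "estimated": "E", "user": "*"}[tag]
        lines.append(f"  [{marker}] {name:<{width}} = {getattr(p, name)!r}")
    estimated = [n for n in p.field_names() if p.provenance.get(n) == "estimated"]
    changed = [n for n in p.field_names() if p.provenance.get(n) == "user"]
    lines.append(f"  estimated fields: {', '.join(estimated) if estimated else '(none)'}")
    lines.append(f"  user-set fields:  {', '.join(changed) if changed else '(none)'}")
    return "\n".join(lines)
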