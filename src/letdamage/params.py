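"""Parameter database for the analytical damage-yield models.

The database maps every (ion, damage class, effect channel) triple to one
fitted parameter set.  Strand-breakage classes (SB, SSB) use the decreasing
form (power-law drop plus an optional log-Gaussian dip), DSB-family classes
use the increasing form (power-law rise divided by an optional logistic
overkill term).  A built-in table covering all 9 x 5 x 3 = 135 combinations
ships with the package; users may load their own CSV/JSON files with the
same schema.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

from .ions import IONS, IonSpecies, get_ion

__all__ = [
    "DamageClass",
    "Channel",
    "ModelForm",
    "DamageSpec",
    "YieldModelParams",
    "ParamDB",
    "ValidationFinding",
    "ValidationReport",
    "ParamValidationError",
    "load_params",
    "save_params",
    "validate_db",
    "BUILTIN",
]

#: Tag accepted by :func:`load_params` for the packaged parameter table.
BUILTIN = "builtin"

_CSV_COLUMNS = ("damage_class", "ion", "channel", "p1", "p2", "p3", "p4", "p5")
_NA = "NA"


class DamageClass(str, enum.Enum):
    SB = "SB"
    SSB = "SSB"
    DSB = "DSB"
    DSB_CLUSTER = "DSB_CLUSTER"
    DSB_SITE = "DSB_SITE"


class Channel(str, enum.Enum):
    TOTAL = "TOTAL"
    DIRECT = "DIRECT"
    INDIRECT = "INDIRECT"


class ModelForm(str, enum.Enum):
    """Functional form of the yield-vs-LET curve."""

    EQ1_DECREASE = "EQ1_DECREASE"
    EQ2_INCREASE = "EQ2_INCREASE"


#: SB and SSB decrease with LET; the DSB family increases (up to overkill).
FORM_BY_CLASS: Mapping[DamageClass, ModelForm] = {
    DamageClass.SB: ModelForm.EQ1_DECREASE,
    DamageClass.SSB: ModelForm.EQ1_DECREASE,
    DamageClass.DSB: ModelForm.EQ2_INCREASE,
    DamageClass.DSB_CLUSTER: ModelForm.EQ2_INCREASE,
    DamageClass.DSB_SITE: ModelForm.EQ2_INCREASE,
}

#: Universal low-LET yields (Gy^-1 Gbp^-1) shared by all ions within a
#: (damage class, channel) pair.
UNIVERSAL_P1: Mapping[tuple[DamageClass, Channel], float] = {
    (DamageClass.SB, Channel.TOTAL): 170.0,
    (DamageClass.SB, Channel.DIRECT): 64.0,
    (DamageClass.SB, Channel.INDIRECT): 106.0,
    (DamageClass.SSB, Channel.TOTAL): 156.0,
    (DamageClass.SSB, Channel.DIRECT): 60.0,
    (DamageClass.SSB, Channel.INDIRECT): 102.0,
    (DamageClass.DSB, Channel.TOTAL): 6.8,
    (DamageClass.DSB, Channel.DIRECT): 2.8,
    (DamageClass.DSB, Channel.INDIRECT): 2.2,
    (DamageClass.DSB_CLUSTER, Channel.TOTAL): 0.07,
    (DamageClass.DSB_CLUSTER, Channel.DIRECT): 0.018,
    (DamageClass.DSB_CLUSTER, Channel.INDIRECT): 0.004,
    (DamageClass.DSB_SITE, Channel.TOTAL): 6.8,
    (DamageClass.DSB_SITE, Channel.DIRECT): 2.8,
    (DamageClass.DSB_SITE, Channel.INDIRECT): 2.2,
}


class ParamValidationError(ValueError):
    """Raised when a parameter source violates the database schema."""

    def __init__(self, message: str, *, where: str | None = None):
        self.where = where
        super().__init__(message if where is None else f"{where}: {message}")


@dataclass(frozen=True, order=True)
class DamageSpec:
    """Key addressing one parameter set: (ion, damage class, channel)."""

    ion: IonSpecies
    damage_class: DamageClass
    channel: Channel

    def label(self) -> str:
        return f"{self.ion.symbol}:{self.damage_class.value}:{self.channel.value}"


@dataclass(frozen=True)
class YieldModelParams:
    """One fitted parameter set.

    ``p2``/``p3`` (power term) and ``p4``/``p5`` (dip or overkill term) are
    pairwise optional: ``None`` means the published fit omitted that term,
    which is distinct from a term with value zero.  In the built-in table
    the power term is omitted only for the direct strand-breakage channel
    of H and He.
    """

    spec: DamageSpec | None
    form: ModelForm
    p1: float
    p2: float | None
    p3: float | None
    p4: float | None
    p5: float | None

    def __post_init__(self) -> None:
        if self.p1 <= 0:
            raise ParamValidationError("p1 must be positive", where=self._where())
        if (self.p2 is None) != (self.p3 is None):
            raise ParamValidationError(
                "p2 and p3 must be both present or both absent", where=self._where()
            )
        if (self.p4 is None) != (self.p5 is None):
            raise ParamValidationError(
                "p4 and p5 must be both present or both absent", where=self._where()
            )
        for name in ("p2", "p3", "p4", "p5"):
            v = getattr(self, name)
            if v is not None and not (v > 0 and math.isfinite(v)):
                raise ParamValidationError(
                    f"{name} must be positive and finite, got {v}", where=self._where()
                )
        if self.form is ModelForm.EQ2_INCREASE and self.p2 is None:
            raise ParamValidationError(
                "the increasing form requires the power term (p2, p3)",
                where=self._where(),
            )

    def _where(self) -> str | None:
        return None if self.spec is None else self.spec.label()

    @property
    def has_power_term(self) -> bool:
        return self.p2 is not None

    @property
    def has_term45(self) -> bool:
        return self.p4 is not None

    def with_spec(self, spec: DamageSpec) -> "YieldModelParams":
        return YieldModelParams(spec, self.form, self.p1, self.p2, self.p3, self.p4, self.p5)


@dataclass(frozen=True)
class ValidationFinding:
    kind: str  # completeness | universal_p1 | positivity | form
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding]

    @property
    def ok(self) -> bool:
        return not self.findings

    def __bool__(self) -> bool:  # truthy when valid, like a passing check
        return self.ok

    def __str__(self) -> str:
        if self.ok:
            return "OK: database valid"
        return "\n".join(f"[{f.kind}] {f.message}" for f in self.findings)


class ParamDB:
    """Immutable-ish mapping from :class:`DamageSpec` to parameter sets."""

    def __init__(self, params: Iterable[YieldModelParams]):
        self._by_spec: dict[DamageSpec, YieldModelParams] = {}
        for p in params:
            if p.spec is None:
                raise ParamValidationError("database entries must carry a DamageSpec")
            if p.spec in self._by_spec:
                raise ParamValidationError("duplicate entry", where=p.spec.label())
            self._by_spec[p.spec] = p

    def get(
        self,
        ion: IonSpecies | str,
        damage_class: DamageClass | str,
        channel: Channel | str = Channel.TOTAL,
    ) -> YieldModelParams:
        spec = make_spec(ion, damage_class, channel)
        try:
            return self._by_spec[spec]
        except KeyError:
            raise KeyError(f"no parameter set for {spec.label()}") from None

    def __getitem__(self, spec: DamageSpec) -> YieldModelParams:
        return self._by_spec[spec]

    def __contains__(self, spec: DamageSpec) -> bool:
        return spec in self._by_spec

    def __iter__(self) -> Iterator[YieldModelParams]:
        return iter(self._by_spec.values())

    def __len__(self) -> int:
        return len(self._by_spec)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParamDB):
            return NotImplemented
        return self._by_spec == other._by_spec

    @property
    def specs(self) -> list[DamageSpec]:
        return list(self._by_spec)


def make_spec(
    ion: IonSpecies | str,
    damage_class: DamageClass | str,
    channel: Channel | str = Channel.TOTAL,
) -> DamageSpec:
    """Build a :class:`DamageSpec`, accepting strings for all fields."""
    if isinstance(ion, str):
        ion = get_ion(ion)
    if isinstance(damage_class, str):
        damage_class = DamageClass(damage_class.upper())
    if isinstance(channel, str):
        channel = Channel(channel.upper())
    return DamageSpec(ion, damage_class, channel)


def _parse_cell(text: str, *, where: str, name: str) -> float | None:
    token = text.strip()
    if token in (_NA, "", "N.A.", "na", "n.a."):
        return None
    try:
        return float(token)
    except ValueError:
        raise ParamValidationError(
            f"malformed number in column {name}: {token!r}", where=where
        ) from None


def _params_from_record(rec: Mapping[str, object], where: str) -> YieldModelParams:
    missing = [c for c in _CSV_COLUMNS[:4] if c not in rec or rec[c] in (None, "")]
    if missing:
        raise ParamValidationError(f"missing fields {missing}", where=where)
    try:
        cls = DamageClass(str(rec["damage_class"]).strip().upper())
    except ValueError:
        raise ParamValidationError(
            f"unknown damage_class {rec['damage_class']!r}", where=where
        ) from None
    try:
        ion = get_ion(str(rec["ion"]))
    except KeyError as exc:
        raise ParamValidationError(str(exc), where=where) from None
    try:
        channel = Channel(str(rec["channel"]).strip().upper())
    except ValueError:
        raise ParamValidationError(
            f"unknown channel {rec['channel']!r}", where=where
        ) from None
    spec = DamageSpec(ion, cls, channel)
    where = spec.label()

    def cell(name: str) -> float | None:
        v = rec.get(name)
        if v is None:
            return None
        if isinstance(v, (int, float)):
            return float(v)
        return _parse_cell(str(v), where=where, name=name)

    p1 = cell("p1")
    if p1 is None:
        raise ParamValidationError("p1 may not be NA", where=where)
    return YieldModelParams(
        spec, FORM_BY_CLASS[cls], p1, cell("p2"), cell("p3"), cell("p4"), cell("p5")
    )


def _load_csv_text(text: str, source_name: str) -> ParamDB:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != list(_CSV_COLUMNS):
        raise ParamValidationError(
            f"expected header {','.join(_CSV_COLUMNS)}", where=source_name
        )
    entries = [
        _params_from_record(row, f"{source_name}:row{i}")
        for i, row in enumerate(reader, start=2)
    ]
    return ParamDB(entries)


def load_params(source: Union[str, Path] = BUILTIN) -> ParamDB:
    """Load a parameter collection.

    Parameters
    ----------
    source
        ``"builtin"`` for the packaged table, or a path to a ``.csv`` or
        ``.json`` file in the documented schema.
    """
    if isinstance(source, str) and source == BUILTIN:
        text = resources.files("letdamage.data").joinpath("parameters.csv").read_text("utf-8")
        db = _load_csv_text(text, "builtin")
        report = validate_db(db)
        if not report.ok:  # pragma: no cover - guards against packaging error
            raise ParamValidationError(f"built-in database invalid:\n{report}")
        return db
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"parameter source not found: {path}")
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text("utf-8"))
        if not isinstance(records, list):
            raise ParamValidationError("JSON source must be an array of objects", where=str(path))
        entries = [
            _params_from_record(rec, f"{path.name}:item{i}")
            for i, rec in enumerate(records)
        ]
        return ParamDB(entries)
    return _load_csv_text(path.read_text("utf-8"), path.name)


def _format_cell(value: float | None) -> str:
    if value is None:
        return _NA
    return repr(value)  # shortest round-trip representation


def _sorted_entries(db: Iterable[YieldModelParams]) -> list[YieldModelParams]:
    cls_order = {c: i for i, c in enumerate(DamageClass)}
    ch_order = {c: i for i, c in enumerate(Channel)}
    return sorted(
        db,
        key=lambda p: (
            cls_order[p.spec.damage_class],
            p.spec.ion.atomic_number,
            ch_order[p.spec.channel],
        ),
    )


def save_params(db: Iterable[YieldModelParams], path: Union[str, Path], format: str | None = None) -> Path:
    """Serialize a parameter collection to CSV or JSON.

    Output is bit-stable: fixed column order, entries sorted by
    (damage class, ion, channel), floats in shortest round-trip form and
    omitted terms written as the literal token ``NA``.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".") or "csv").lower()
    entries = _sorted_entries(db)
    if fmt == "csv":
        out = [",".join(_CSV_COLUMNS)]
        for p in entries:
            out.append(
                ",".join(
                    [
                        p.spec.damage_class.value,
                        p.spec.ion.symbol,
                        p.spec.channel.value,
                        _format_cell(p.p1),
                        _format_cell(p.p2),
                        _format_cell(p.p3),
                        _format_cell(p.p4),
                        _format_cell(p.p5),
                    ]
                )
            )
        path.write_text("\n".join(out) + "\n", "utf-8")
    elif fmt == "json":
        records = [
            {
                "damage_class": p.spec.damage_class.value,
                "ion": p.spec.ion.symbol,
                "channel": p.spec.channel.value,
                "p1": p.p1,
                "p2": p.p2,
                "p3": p.p3,
                "p4": p.p4,
                "p5": p.p5,
            }
            for p in entries
        ]
        path.write_text(json.dumps(records, indent=1) + "\n", "utf-8")
    else:
        raise ValueError(f"unsupported format {fmt!r}; use csv or json")
    return path


def validate_db(db: Iterable[YieldModelParams]) -> ValidationReport:
    """Check completeness, universal-p1 consistency and form assignment.

    An empty report means the collection is a complete, consistent database.
    """
    findings: list[ValidationFinding] = []
    by_spec: dict[DamageSpec, YieldModelParams] = {}
    for p in db:
        if p.spec is None:
            findings.append(ValidationFinding("completeness", "entry without a DamageSpec"))
            continue
        by_spec[p.spec] = p

    for cls in DamageClass:
        for ion in IONS:
            for ch in Channel:
                spec = DamageSpec(ion, cls, ch)
                if spec not in by_spec:
                    findings.append(
                        ValidationFinding("completeness", f"missing parameter set {spec.label()}")
                    )

    for (cls, ch), expected_groups in _p1_groups(by_spec).items():
        if len(expected_groups) > 1:
            detail = "; ".join(
                f"p1={v} for {', '.join(sorted(s))}" for v, s in sorted(expected_groups.items())
            )
            findings.append(
                ValidationFinding(
                    "universal_p1",
                    f"({cls.value}, {ch.value}): p1 not universal across ions: {detail}",
                )
            )

    for spec, p in by_spec.items():
        if p.form is not FORM_BY_CLASS[spec.damage_class]:
            findings.append(
                ValidationFinding(
                    "form",
                    f"{spec.label()}: form {p.form.value} inconsistent with damage class",
                )
            )
    return ValidationReport(findings)


def _p1_groups(
    by_spec: Mapping[DamageSpec, YieldModelParams]
) -> dict[tuple[DamageClass, Channel], dict[float, set[str]]]:
    groups: dict[tuple[DamageClass, Channel], dict[float, set[str]]] = {}
    for spec, p in by_spec.items():
        bucket = groups.setdefault((spec.damage_class, spec.channel), {})
        bucket.setdefault(p.p1, set()).add(spec.ion.symbol)
    return groups
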