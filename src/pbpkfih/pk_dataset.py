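"""Concentration-time data containers and long-format CSV readers/writers.

The study design emulated throughout the package is a single-ascending-dose
first-in-human trial: seven dose groups (2, 6, 12, 24, 40, 60, 90 mg), two
subjects at 2 mg and eight otherwise, with rich plasma sampling over 0-96 h
and an assay lower limit of quantification (LLOQ). Concentrations below the
LLOQ are carried as explicit BLQ markers, never silently as zeros.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, NoQuantifiableData, ValidationError

#: default sampling schedule (h post-dose) of the emulated trial
DEFAULT_SCHEDULE: tuple[float, ...] = (
    0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 12.0,
    24.0, 36.0, 48.0, 72.0, 96.0,
)

#: default dose escalation (mg) and group sizes of the emulated trial
DEFAULT_DOSES: tuple[float, ...] = (2.0, 6.0, 12.0, 24.0, 40.0, 60.0, 90.0)
DEFAULT_GROUP_SIZES: tuple[int, ...] = (2, 8, 8, 8, 8, 8, 8)

CSV_HEADER = ("subject", "dose_mg", "time_h", "conc_ng_ml")
DEFAULT_BLQ_TOKEN = "BLQ"


@dataclass(frozen=True)
class ConcentrationProfile:
    """One subject's dose and sampled plasma concentration-time points.

    ``concentrations[i]`` is ignored (stored as NaN) wherever ``blq[i]`` is
    True; those points are below the limit of quantification.
    """

    subject_id: str
    dose_mg: float
    times: np.ndarray
    concentrations: np.ndarray
    blq: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        b = np.asarray(self.blq, dtype=bool)
        if not (t.ndim == 1 and c.shape == t.shape and b.shape == t.shape):
            raise ValidationError("times/concentrations/blq must be 1-D and equal length")
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValidationError(f"times must be strictly increasing and >= 0 (subject {self.subject_id})")
        if np.any(c[~b] < 0) or np.any(~np.isfinite(c[~b])):
            raise ValidationError(f"quantified concentrations must be finite and >= 0 (subject {self.subject_id})")
        if self.dose_mg <= 0:
            raise ValidationError(f"dose must be positive (subject {self.subject_id})")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", np.where(b, np.nan, c))
        object.__setattr__(self, "blq", b)

    @property
    def n_quantified(self) -> int:
        return int(np.count_nonzero(~self.blq))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationProfile):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.dose_mg == other.dose_mg
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.blq, other.blq)
            and np.allclose(
                self.concentrations[~self.blq], other.concentrations[~other.blq],
                rtol=0, atol=0, equal_nan=False,
            )
        )


@dataclass(frozen=True)
class DoseGroup:
    """All profiles sharing one dose level."""

    dose_mg: float
    profiles: list[ConcentrationProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("a dose group needs at least one profile")
        for p in self.profiles:
            if p.dose_mg != self.dose_mg:
                raise ValidationError(
                    f"subject {p.subject_id} dosed at {p.dose_mg} mg in the {self.dose_mg} mg group"
                )

    @property
    def n(self) -> int:
        return len(self.profiles)


@dataclass(frozen=True)
class StudyDesign:
    """Dose levels, group sizes, sampling schedule and assay LLOQ."""

    dose_levels: tuple[float, ...] = DEFAULT_DOSES
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    lloq: float = 0.05

    def __post_init__(self) -> None:
        if np.any(np.diff(self.dose_levels) <= 0):
            raise ValidationError("dose_levels must be strictly increasing")
        if len(self.group_sizes) != len(self.dose_levels):
            raise ValidationError("group_sizes and dose_levels must have equal length")
        if self.lloq <= 0:
            raise ValidationError("lloq must be positive")


@dataclass(frozen=True)
class PreparedProfile:
    """A profile with the BLQ policy applied, ready for NCA.

    ``analysis_times``/``analysis_concs`` are the points entering AUC and
    terminal-slope computations; the untouched source profile is retained.
    """

    source: ConcentrationProfile
    analysis_times: np.ndarray
    analysis_concs: np.ndarray
    policy: dict = field(default_factory=dict)

    @property
    def subject_id(self) -> str:
        return self.source.subject_id

    @property
    def dose_mg(self) -> float:
        return self.source.dose_mg


def blq_policy(profile: ConcentrationProfile) -> PreparedProfile:
    """Apply the standard BLQ convention ahead of NCA.

    BLQ points before the first quantifiable concentration are set to 0
    (pre-absorption samples); BLQ points after it are excluded from AUC and
    terminal-slope computations but stay on record in the source profile.
    Idempotent: preparing an already-prepared profile's source again gives the
    same analysis arrays.
    """
    quant = ~profile.blq
    if not quant.any():
        raise NoQuantifiableData(f"subject {profile.subject_id}: all points BLQ")
    first_q = int(np.argmax(quant))
    keep = quant.copy()
    keep[:first_q] = True  # leading BLQ kept as zeros
    times = profile.times[keep]
    concs = np.where(profile.blq, 0.0, profile.concentrations)[keep]
    meta = {
        "leading_blq_as_zero": int(first_q),
        "excluded_blq": int(np.count_nonzero(profile.blq[first_q:])),
        "policy": "leading BLQ -> 0; embedded/trailing BLQ excluded",
    }
    return PreparedProfile(profile, times, concs, meta)


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def _resolve_columns(header: list[str], dialect: dict[str, str] | None) -> dict[str, int]:
    names = {"subject": "subject", "dose": "dose_mg", "time": "time_h", "conc": "conc_ng_ml"}
    if dialect:
        names.update(dialect)
    idx = {}
    for key, col in names.items():
        if col not in header:
            raise FormatError(f"missing required column '{col}' (for {key}); header was {header}")
        idx[key] = header.index(col)
    return idx


def read_profiles(
    path,
    dialect: dict[str, str] | None = None,
    blq_token: str = DEFAULT_BLQ_TOKEN,
    lloq: float | None = None,
) -> list[DoseGroup]:
    """Read a long-format CSV into dose groups.

    Rows are grouped by (dose, subject) and time-sorted per subject. A
    concentration equal to ``blq_token`` (case-insensitive), or numerically
    below ``lloq`` when one is given, becomes a BLQ marker. Malformed rows
    raise :class:`FormatError` naming the 1-based line number.
    """
    rows: dict[tuple[float, str], list[tuple[float, float, bool]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError(f"{path}: empty file")
        idx = _resolve_columns([h.strip() for h in header], dialect)
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            try:
                subject = row[idx["subject"]].strip()
                dose = float(row[idx["dose"]])
                time = float(row[idx["time"]])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: unparseable row: {exc}") from exc
            raw = row[idx["conc"]].strip()
            if raw.upper() == blq_token.upper():
                conc, is_blq = math.nan, True
            else:
                try:
                    conc = float(raw)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric concentration {raw!r}"
                    ) from exc
                is_blq = lloq is not None and conc < lloq
            rows.setdefault((dose, subject), []).append((time, conc, is_blq))

    groups: dict[float, list[ConcentrationProfile]] = {}
    for (dose, subject), pts in rows.items():
        pts.sort(key=lambda p: p[0])
        times = [p[0] for p in pts]
        if len(set(times)) != len(times):
            dup = sorted({t for t in times if times.count(t) > 1})
            raise ValidationError(f"duplicate (subject, time) for subject {subject} at t={dup}")
        profile = ConcentrationProfile(
            subject_id=subject,
            dose_mg=dose,
            times=np.array(times),
            concentrations=np.array([p[1] for p in pts]),
            blq=np.array([p[2] for p in pts]),
        )
        groups.setdefault(dose, []).append(profile)
    return [
        DoseGroup(dose, sorted(profs, key=lambda p: p.subject_id))
        for dose, profs in sorted(groups.items())
    ]


def write_profiles(groups: list[DoseGroup], path, blq_token: str = DEFAULT_BLQ_TOKEN):
    """Write dose groups as a long-format CSV; inverse of :func:`read_profiles`."""
    if not groups:
        raise ValidationError("nothing to write: empty group list")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for group in groups:
            for p in group.profiles:
                for t, c, b in zip(p.times, p.concentrations, p.blq):
                    writer.writerow(
                        [p.subject_id, fmt_num(p.dose_mg), fmt_num(t),
                         blq_token if b else repr(float(c))]
                    )
    return path


def fmt_num(x: float) -> str:
    """Render a float without losing round-trip precision."""
    return repr(float(x))


def all_profiles(groups: list[DoseGroup]) -> list[ConcentrationProfile]:
    return [p for g in groups for p in g.profiles]
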