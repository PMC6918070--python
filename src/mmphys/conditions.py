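"""Growth conditions, shift schedules, and sampling configuration.

A :class:`GrowthCondition` bundles everything the simulator needs to know
about one nutrient/antibiotic environment: the population doubling time
(``tau_mean``), the replication (C) and post-replication (D) period means,
the per-origin initiation volume (``si_mean``), cell width, septum-position
statistics, and a coefficient of variation for each noisy quantity.

Conditions can be defined in plain-text config files (INI sections, one per
condition or schedule) so that simulation runs are reproducible from a
single file.
"""

from __future__ import annotations

import configparser
import math
from dataclasses import dataclass, replace

__all__ = [
    "GrowthCondition",
    "ShiftSchedule",
    "SamplingConfig",
    "CONDITIONS",
    "DEFAULT_CONDITION",
    "load_config",
    "dump_config",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class GrowthCondition:
    """Parameter set for one steady-state growth condition.

    Means are in minutes (times), micrometres (width) or cubic micrometres
    (initiation size per origin); CVs are dimensionless fractions in [0, 1).
    ``si_mean`` is the per-origin cell volume at replication initiation --
    the quantity that is invariant across conditions in the threshold model.
    """

    name: str
    tau_mean: float
    si_mean: float = 1.2
    C_mean: float = 40.0
    D_mean: float = 20.0
    width_mean: float = 0.9
    septum_mean: float = 0.5
    lambda_cv: float = 0.07
    si_cv: float = 0.08
    C_cv: float = 0.12
    D_cv: float = 0.25
    width_cv: float = 0.035
    septum_cv: float = 0.04

    def __post_init__(self) -> None:
        for attr in ("tau_mean", "si_mean", "C_mean", "D_mean", "width_mean"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive, got {getattr(self, attr)}")
        for attr in ("lambda_cv", "si_cv", "C_cv", "D_cv", "width_cv", "septum_cv"):
            cv = getattr(self, attr)
            if not 0.0 <= cv < 1.0:
                raise ValueError(f"{attr} must lie in [0, 1), got {cv}")
        if not 0.0 < self.septum_mean < 1.0:
            raise ValueError(f"septum_mean must lie in (0, 1), got {self.septum_mean}")

    @property
    def growth_rate(self) -> float:
        """Population growth rate λ = ln 2 / τ in 1/min."""
        return LN2 / self.tau_mean

    def noiseless(self) -> "GrowthCondition":
        """Copy of this condition with every CV set to zero."""
        return replace(
            self,
            lambda_cv=0.0, si_cv=0.0, C_cv=0.0, D_cv=0.0,
            width_cv=0.0, septum_cv=0.0,
        )


@dataclass(frozen=True)
class ShiftSchedule:
    """Ordered nutrient-shift schedule.

    ``segments`` is a sequence of ``(start_time_min, GrowthCondition)`` with
    strictly increasing start times, the first at 0.  A segment whose
    doubling time is longer than its predecessor's is a downshift: growth
    and replication-fork progression pause for a duration drawn uniformly
    from ``pause_after_downshift`` (min), then resume at the new condition's
    parameters.  Upshifts take effect immediately.
    """

    segments: tuple
    pause_after_downshift: tuple = (60.0, 120.0)

    def __post_init__(self) -> None:
        if len(self.segments) < 2:
            raise ValueError("a shift schedule needs at least 2 segments")
        starts = [s[0] for s in self.segments]
        if starts[0] != 0:
            raise ValueError("first segment must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")
        pause = self.pause_after_downshift
        if isinstance(pause, (int, float)):
            object.__setattr__(self, "pause_after_downshift", (float(pause), float(pause)))
        lo, hi = self.pause_after_downshift
        if lo < 0 or hi < lo:
            raise ValueError("pause range must satisfy 0 <= lo <= hi")

    def condition_at(self, t: float) -> GrowthCondition:
        cond = self.segments[0][1]
        for start, c in self.segments:
            if t >= start:
                cond = c
        return cond

    def downshift_times(self):
        """Start times of segments that slow growth relative to the previous one."""
        out = []
        for (t0, c0), (t1, c1) in zip(self.segments, self.segments[1:]):
            if c1.tau_mean > c0.tau_mean:
                out.append(t1)
        return out


@dataclass(frozen=True)
class SamplingConfig:
    """Frame-sampling configuration for simulated time-lapse observation.

    Phase-contrast frames (cell length) every ``phase_interval`` min and
    fluorescence frames (replisome focus counts) every ``fluor_interval``
    min, the latter an integer multiple of the former.
    """

    phase_interval: float = 1.5
    fluor_interval: float = 3.0
    total_duration: float | None = None

    def __post_init__(self) -> None:
        if self.phase_interval <= 0 or self.fluor_interval <= 0:
            raise ValueError("sampling intervals must be positive")
        ratio = self.fluor_interval / self.phase_interval
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fluor_interval must be an integer multiple of phase_interval")

    @property
    def fluor_every(self) -> int:
        return int(round(self.fluor_interval / self.phase_interval))


def _bsub(name, tau, C, D, width, **kw) -> GrowthCondition:
    return GrowthCondition(name=name, tau_mean=tau, C_mean=C, D_mean=D,
                           width_mean=width, **kw)


#: Built-in B. subtilis-like conditions. All share si_mean (the invariant
#: per-origin initiation volume); doubling times span the ~24-65 min range,
#: widths differ slightly so that only the initiation *volume* per ori, not
#: the length per ori, is constant across conditions.
CONDITIONS = {
    "glycerol_rich": _bsub("glycerol_rich", 24.0, 40.0, 18.0, 1.00),
    "mannose": _bsub("mannose", 38.0, 40.0, 20.0, 0.92),
    "succinate": _bsub("succinate", 45.0, 42.0, 22.0, 0.88),
    "succinate_rich": _bsub("succinate_rich", 30.0, 40.0, 20.0, 0.95),
    "succinate_minimal": _bsub("succinate_minimal", 65.0, 48.0, 26.0, 0.85),
}

DEFAULT_CONDITION = CONDITIONS["mannose"]

_FLOAT_FIELDS = (
    "tau_mean", "si_mean", "C_mean", "D_mean", "width_mean", "septum_mean",
    "lambda_cv", "si_cv", "C_cv", "D_cv", "width_cv", "septum_cv",
)


def load_config(path):
    """Read conditions and shift schedules from an INI-style config file.

    Sections named ``[condition:NAME]`` define a :class:`GrowthCondition`;
    sections named ``[schedule:NAME]`` define a :class:`ShiftSchedule` with
    keys ``segments`` (comma-separated ``start:condition_name`` pairs) and
    optional ``pause`` (``lo-hi`` minutes).

    Returns a dict name -> GrowthCondition | ShiftSchedule.
    """
    parser = configparser.ConfigParser()
    with open(path, "r", encoding="utf-8") as fh:
        parser.read_file(fh)
    out: dict = {}
    for section in parser.sections():
        if section.startswith("condition:"):
            name = section.split(":", 1)[1]
            kw = {k: float(v) for k, v in parser[section].items() if k in _FLOAT_FIELDS}
            out[name] = GrowthCondition(name=name, **kw)
    for section in parser.sections():
        if section.startswith("schedule:"):
            name = section.split(":", 1)[1]
            seg_spec = parser[section]["segments"]
            segments = []
            for part in seg_spec.split(","):
                start, cname = part.strip().split(":")
                cond = out.get(cname.strip()) or CONDITIONS.get(cname.strip())
                if cond is None:
                    raise KeyError(f"unknown condition {cname!r} in schedule {name!r}")
                segments.append((float(start), cond))
            pause = parser[section].get("pause", "60-120")
            lo, _, hi = pause.partition("-")
            pause_range = (float(lo), float(hi or lo))
            out[name] = ShiftSchedule(segments=tuple(segments),
                                      pause_after_downshift=pause_range)
    return out


def dump_config(entries: dict, path) -> None:
    """Write conditions/schedules back to the INI format read by load_config."""
    parser = configparser.ConfigParser()
    for name, obj in entries.items():
        if isinstance(obj, GrowthCondition):
            parser[f"condition:{name}"] = {
                f: repr(getattr(obj, f)) for f in _FLOAT_FIELDS
            }
    for name, obj in entries.items():
        if isinstance(obj, ShiftSchedule):
            parser[f"schedule:{name}"] = {
                "segments": ", ".join(f"{t:g}:{c.name}" for t, c in obj.segments),
                "pause": f"{obj.pause_after_downshift[0]:g}-{obj.pause_after_downshift[1]:g}",
            }
    with open(path, "w", encoding="utf-8") as fh:
        parser.write(fh)
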