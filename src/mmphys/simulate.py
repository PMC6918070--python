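"""Stochastic single-cell growth and replication-cycle simulator.

The model is the initiator-threshold ("initiation mass") picture of
bacterial replication control:

* cell volume grows exponentially at a per-generation rate λ (balanced
  biosynthesis);
* an initiator pool accumulates in proportion to volume growth, divided
  over the current number of origins; when the per-origin accumulated
  volume reaches a threshold δ, all origins fire simultaneously (the origin
  count doubles), the overshoot carries into the next cycle, and a fresh δ
  is drawn.  The steady-state per-origin volume at initiation is the fixed
  point of v ← v/2 + δ, i.e. 2δ, so δ is parameterized as si_mean/2;
* each initiation cohort replicates for a C period, then commits a division
  a D period after termination; the earliest pending commitment executes
  the next division, which splits the volume by the (noisy) septum
  fraction and halves the origin count;
* a nutrient downshift pauses growth and fork progression for a sampled
  interval; divisions already in their D period proceed on schedule, and
  initiation resumes only once the threshold is reached again.

Mother-machine semantics: one daughter (the old-pole cell) is tracked per
division.  Frames sample length at the phase-contrast interval and
replisome-pair focus counts at the fluorescence interval.

Every simulation takes an explicit integer seed; identical seeds give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import GrowthCondition, SamplingConfig, ShiftSchedule
from .markerfreq import MarkerFrequencyData
from .physiology import ODTrace, length_from_volume

__all__ = [
    "InitiatorState",
    "accumulate_and_fire",
    "SimulationResult",
    "SimulationError",
    "simulate_steady_state",
    "simulate_shift",
    "simulate_qpcr",
    "simulate_turbidostat",
]

LN2 = math.log(2.0)
_TIE = 1e-6  # min; events closer than this are simultaneous (divisions first)


class SimulationError(RuntimeError):
    """Raised when a parameter set produces non-viable dynamics."""


def _truncated_normal(rng: np.random.Generator, mean: float, cv: float,
                      k_sd: float = 4.0) -> float:
    """Normal(mean, cv*mean) truncated at ±k_sd SD by resampling."""
    if cv == 0.0:
        return mean
    sd = cv * mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= k_sd * sd and x > 0:
            return x
    raise SimulationError("truncated-normal resampling failed")


# ---------------------------------------------------------------------------
# threshold primitive
# ---------------------------------------------------------------------------

@dataclass
class InitiatorState:
    """Per-origin initiator accumulation state.

    ``accum`` is the per-origin volume accumulated since the last
    initiation, ``delta`` the current per-origin increment threshold, and
    ``n_ori`` the number of origins that will fire at the next initiation.
    """

    accum: float
    delta: float
    n_ori: int


def accumulate_and_fire(state: InitiatorState, added_volume: float,
                        new_delta: float | None = None):
    """Add total cell volume growth to the initiator pool; fire if the
    per-origin threshold is reached.

    The added volume is shared over the ``n_ori`` origins.  On firing the
    origin count doubles, the overshoot beyond δ carries over, and the
    threshold is replaced by ``new_delta`` (default: unchanged, the
    noiseless case).  Returns ``(state, fired)``.
    """
    if added_volume < 0:
        raise ValueError("added_volume must be non-negative")
    state.accum += added_volume / state.n_ori
    fired = state.accum >= state.delta
    if fired:
        carry = state.accum - state.delta
        state.n_ori *= 2
        state.accum = carry
        if new_delta is not None:
            state.delta = new_delta
    return state, fired


# ---------------------------------------------------------------------------
# event-driven lineage engine
# ---------------------------------------------------------------------------

@dataclass
class _Round:
    """One initiation cohort: all origins firing simultaneously."""

    t_init: float
    S_i: float           # cell volume at initiation
    n_ori: int           # origins firing (pre-doubling count)
    s_i: float           # S_i / n_ori
    C: float
    D: float
    t_term: float        # extended by pause overlap
    t_div_commit: float
    n_pairs: int         # current fork-pair multiplicity in this lineage
    cell_id: int
    div_count_at_init: int


@dataclass
class SimulationResult:
    """Simulator output tables.

    ``cells``: one row per completed generation (ground truth).
    ``initiations``: one row per initiation cohort with its resolved
    division (C, D, n_oc, sizes).
    ``frames``: frame-sampled observations (``None`` if no sampling
    config was given).  ``pauses``: downshift pause windows per lineage.
    """

    cells: pd.DataFrame
    initiations: pd.DataFrame
    frames: pd.DataFrame | None
    pauses: list = field(default_factory=list)


def _simulate_lineage(lineage: int, segments, pauses, t_end, sampling,
                      rng, max_generations=None, refractory: float = 6.0):
    """Simulate one mother-machine lineage; returns (cells, inits, frames).

    ``segments``: list of (t_start, GrowthCondition); ``pauses``: list of
    (t0, t1) growth/fork pause windows (downshifts).
    """
    cond = segments[0][1]
    # boundaries where rates change: segment starts (beyond 0) + pause ends
    boundaries = sorted({s[0] for s in segments[1:]} | {p[1] for p in pauses})

    def in_pause(t):
        return any(p0 - _TIE < t < p1 - _TIE for p0, p1 in pauses)

    def cond_at(t):
        c = segments[0][1]
        for start, cc in segments:
            if t >= start - _TIE:
                c = cc
        return c

    t = 0.0
    # Seed the lineage at the canonical (Cooper-Helmstetter-style) steady
    # state of the noiseless model: a newborn cell of the right size, with
    # the in-flight rounds and pending division commitments a steady-state
    # cell would carry.  The threshold dynamics are neutral in the origin
    # number, so without this backlog the first C+D minutes of unopposed
    # initiations would drift the lineage to twice the canonical ploidy.
    CD = cond.C_mean + cond.D_mean
    tau = cond.tau_mean
    k_overlap = max(1, math.ceil(CD / tau - 1e-12))
    n_init = 2 ** (k_overlap - 1)      # origins firing at a steady initiation
    a_i = k_overlap * tau - CD         # initiation age within a generation
    n_ori = n_init
    delta = _truncated_normal(rng, cond.si_mean / 2.0, cond.si_cv)
    V = cond.si_mean * n_init * math.exp(cond.growth_rate * (tau - a_i)) / 2.0
    accum = V / n_init - cond.si_mean / 2.0
    W = _truncated_normal(rng, cond.width_mean, cond.width_cv)
    lam = _truncated_normal(rng, cond.growth_rate, cond.lambda_cv)
    cell_id = 0
    t_birth = 0.0
    V_birth = V
    lam_birth = lam
    rounds: list[_Round] = []
    for j in range(1, k_overlap + 1):
        t0 = a_i - j * tau
        if t0 + CD <= _TIE:
            continue
        n_pairs = n_init // (2 ** j)   # halved at each division since firing
        rounds.append(_Round(
            t_init=t0, S_i=cond.si_mean * n_init, n_ori=n_init,
            s_i=cond.si_mean, C=cond.C_mean, D=cond.D_mean,
            t_term=t0 + cond.C_mean, t_div_commit=t0 + CD,
            n_pairs=n_pairs, cell_id=-1, div_count_at_init=-j,
        ))
    divisions_done = 0
    last_division = -math.inf
    bnd_idx = 0

    cells_rows, init_rows, frame_rows = [], [], []
    next_frame = 0.0 if sampling is not None else math.inf
    fluor_every = sampling.fluor_every if sampling is not None else 1
    frame_count = 0

    def active_pairs(tt):
        return sum(r.n_pairs for r in rounds if r.t_init - _TIE <= tt < r.t_term)

    def emit_frames(upto, lam_eff, t_ref, V_ref):
        nonlocal next_frame, frame_count
        while next_frame < upto - _TIE:
            Vf = V_ref * math.exp(lam_eff * (next_frame - t_ref))
            row = {
                "time_min": next_frame,
                "lineage": lineage,
                "cell_id": f"{lineage}.{cell_id}",
                "length_um": length_from_volume(Vf, W),
                "width_um": W,
            }
            if frame_count % fluor_every == 0:
                k = active_pairs(next_frame)
                row["pair_count"] = float(k)
                if k:
                    base = (2 * np.arange(1, k + 1) - 1) / (2.0 * k)
                    pos = np.clip(base + rng.normal(0.0, 0.05, size=k), 0.0, 1.0)
                    row["focus_positions"] = ";".join(f"{p:.4f}" for p in np.sort(pos))
                else:
                    row["focus_positions"] = ""
            else:
                row["pair_count"] = np.nan
                row["focus_positions"] = ""
            frame_rows.append(row)
            next_frame += sampling.phase_interval
            frame_count += 1

    guard = 0
    while t < t_end - _TIE:
        guard += 1
        if guard > 2_000_000:
            raise SimulationError("event budget exceeded (runaway dynamics)")
        if max_generations is not None and divisions_done >= max_generations + 1:
            break
        if len(rounds) > 64 or V <= 0:
            raise SimulationError("non-viable dynamics (origin/volume runaway)")

        paused = in_pause(t)
        lam_eff = 0.0 if paused else lam

        # candidate events
        if lam_eff > 0 and accum < delta:
            V_target = V + n_ori * (delta - accum)
            t_init = t + math.log(V_target / V) / lam_eff
        elif lam_eff > 0:
            t_init = t  # threshold already met (carry-over overshoot)
        else:
            t_init = math.inf
        t_div = min((r.t_div_commit for r in rounds), default=math.inf)
        # septation refractory period: a commitment landing hard on the
        # heels of the previous division executes after a short delay
        t_div = max(t_div, last_division + refractory)
        t_bound = boundaries[bnd_idx] if bnd_idx < len(boundaries) else math.inf
        t_event = min(t_init, t_div, t_bound, t_end)

        # emit frames strictly before the event, then advance growth state
        if sampling is not None:
            emit_frames(min(t_event, t_end), lam_eff, t, V)
        dt = t_event - t
        if dt > 0:
            growth = V * (math.exp(lam_eff * dt) - 1.0)
            V += growth
            accum += growth / n_ori
            t = t_event

        if t >= t_end - _TIE:
            break

        # --- dispatch; divisions take priority at ties -------------------
        if t_div <= t_event + _TIE and rounds:
            r = min(rounds, key=lambda x: x.t_div_commit)
            rounds.remove(r)
            f = _truncated_normal(rng, cond.septum_mean, cond.septum_cv)
            V_div = V
            cells_rows.append({
                "lineage": lineage,
                "cell_id": f"{lineage}.{cell_id}",
                "parent_id": f"{lineage}.{cell_id - 1}" if cell_id else "",
                "t_birth_min": t_birth,
                "t_div_min": t,
                "V_birth_um3": V_birth,
                "V_div_um3": V_div,
                "width_um": W,
                "growth_rate_per_min": lam_birth,
                "septum_fraction": f,
                "condition": cond.name,
            })
            if r.cell_id >= 0:  # seeded pre-t=0 rounds are not observable
                init_rows.append({
                    "lineage": lineage,
                    "cell_id": f"{lineage}.{r.cell_id}",
                    "t_init_min": r.t_init,
                    "S_i_um3": r.S_i,
                    "n_ori": r.n_ori,
                    "s_i_um3": r.s_i,
                    "C_min": r.t_term - r.t_init,  # pause-extended effective C
                    "C_sampled_min": r.C,
                    "D_min": r.D,
                    "t_term_min": r.t_term,
                    "t_div_min": t,
                    "S_d_um3": V_div,
                    "n_oc": divisions_done - r.div_count_at_init,
                })
            divisions_done += 1
            last_division = t
            if n_ori % 2:
                # a lone origin cannot be split between daughters
                raise SimulationError("division with odd origin count")
            n_ori //= 2
            V *= f
            survivors = []
            for rr in rounds:
                if rr.t_init - _TIE <= t < rr.t_term:  # active forks split
                    if rr.n_pairs == 1:
                        if rng.random() < 0.5:
                            survivors.append(rr)
                        continue
                    rr.n_pairs //= 2
                survivors.append(rr)
            rounds = survivors
            cell_id += 1
            t_birth = t
            V_birth = V
            W = _truncated_normal(rng, cond.width_mean, cond.width_cv)
            lam = _truncated_normal(rng, cond.growth_rate, cond.lambda_cv)
            lam_birth = lam
            continue

        if t_init <= t_event + _TIE and not paused:
            accum = delta  # land exactly on the threshold
            C = _truncated_normal(rng, cond.C_mean, cond.C_cv)
            D = _truncated_normal(rng, cond.D_mean, cond.D_cv)
            rounds.append(_Round(
                t_init=t, S_i=V, n_ori=n_ori, s_i=V / n_ori, C=C, D=D,
                t_term=t + C, t_div_commit=t + C + D, n_pairs=n_ori,
                cell_id=cell_id, div_count_at_init=divisions_done,
            ))
            n_ori *= 2
            accum = 0.0
            delta = _truncated_normal(rng, cond.si_mean / 2.0, cond.si_cv)
            continue

        if t_bound <= t_event + _TIE:
            bnd_idx += 1
            cond = cond_at(t)
            # growth rate changes immediately at a shift (and a new rate
            # applies once any pause ends)
            lam = _truncated_normal(rng, cond.growth_rate, cond.lambda_cv)
            # freeze fork progression across a pause that starts now
            for p0, p1 in pauses:
                if abs(t - p0) < _TIE:
                    shift = p1 - p0
                    for rr in rounds:
                        if rr.t_term > t + _TIE:
                            rr.t_term += shift
                            rr.t_div_commit += shift
            continue

    cells = pd.DataFrame(cells_rows)
    inits = pd.DataFrame(init_rows)
    frames = pd.DataFrame(frame_rows) if sampling is not None else None
    return cells, inits, frames


def _finalize(parts, pauses):
    cells = pd.concat([p[0] for p in parts], ignore_index=True)
    inits = pd.concat([p[1] for p in parts], ignore_index=True)
    if parts[0][2] is not None:
        frames = pd.concat([p[2] for p in parts], ignore_index=True)
    else:
        frames = None
    return SimulationResult(cells=cells, initiations=inits, frames=frames,
                            pauses=pauses)


def simulate_steady_state(condition: GrowthCondition,
                          sampling: SamplingConfig | None = None,
                          n_generations: int = 50,
                          n_lineages: int = 1,
                          seed: int = 0) -> SimulationResult:
    """Simulate mother-machine lineages under one steady growth condition.

    Each of ``n_lineages`` independent lineages is run until
    ``n_generations`` completed cell generations have been recorded.
    Set ``sampling`` to also produce frame-sampled traces.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n_lineages)
    t_end = condition.tau_mean * (n_generations + 20) * 2.0
    parts = []
    for k in range(n_lineages):
        rng = np.random.default_rng(seeds[k])
        parts.append(_simulate_lineage(
            k, [(0.0, condition)], [], t_end, sampling, rng,
            max_generations=n_generations))
    return _finalize(parts, [])


def simulate_shift(schedule: ShiftSchedule,
                   sampling: SamplingConfig | None = None,
                   total_duration: float | None = None,
                   n_lineages: int = 1,
                   seed: int = 0) -> SimulationResult:
    """Simulate lineages through a nutrient-shift schedule.

    At every downshift each lineage pauses growth and fork progression for
    a duration drawn uniformly from the schedule's pause range; divisions
    whose rounds already terminated proceed on schedule during the pause.
    ``total_duration`` defaults to the last segment start plus 8 h.
    """
    if total_duration is None:
        total_duration = schedule.segments[-1][0] + 480.0
    if sampling is not None and sampling.total_duration is not None:
        total_duration = sampling.total_duration
    seeds = np.random.SeedSequence(seed).spawn(n_lineages)
    down = schedule.downshift_times()
    lo, hi = schedule.pause_after_downshift
    parts, pauses_all = [], []
    for k in range(n_lineages):
        rng = np.random.default_rng(seeds[k])
        pauses = [(t0, t0 + (rng.uniform(lo, hi) if hi > lo else lo))
                  for t0 in down]
        pauses_all.append(pauses)
        parts.append(_simulate_lineage(
            k, list(schedule.segments), pauses, total_duration, sampling, rng))
    return _finalize(parts, pauses_all)


# ---------------------------------------------------------------------------
# qPCR marker frequencies and turbidostat OD traces
# ---------------------------------------------------------------------------

def simulate_qpcr(C: float, tau: float, positions, noise_cv: float = 0.0,
                  seed: int = 0, labels=None) -> MarkerFrequencyData:
    """Simulate relative locus copy numbers in an exponential population.

    The expected frequency at normalized position m (ori = 0, ter = 1) is
    2^{C(1−m)/τ}, multiplied by mean-one lognormal noise with the given CV
    so the ter frequency's expectation stays 1.
    """
    if C < 0 or tau <= 0:
        raise ValueError("need C >= 0 and tau > 0")
    m = np.abs(np.asarray(positions, dtype=float))
    if np.any(m > 1):
        raise ValueError("positions must lie in [-1, 1]")
    freq = 2.0 ** (C * (1.0 - m) / tau)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        freq = freq * rng.lognormal(-sigma**2 / 2.0, sigma, size=m.shape)
    if labels is None:
        labels = [f"m{mi:.2f}" for mi in m]
    return MarkerFrequencyData(labels=list(labels), positions=m,
                               frequencies=freq)


def simulate_turbidostat(tau: float, od_low: float = 0.05,
                         od_high: float = 0.2, sample_interval: float = 1.0,
                         n_cycles: int = 10, noise_cv: float = 0.0,
                         seed: int = 0) -> ODTrace:
    """Simulate a turbidostat run as a batch-growth repeater.

    OD grows as I0·2^{t/τ} from ``od_low`` and is instantaneously diluted
    back to ``od_low`` when it crosses ``od_high``; samples are taken on a
    fixed grid with multiplicative lognormal observation noise.
    """
    if not 0 < od_low < od_high:
        raise ValueError("need 0 < od_low < od_high")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    period = tau * math.log2(od_high / od_low)
    dilutions = np.arange(1, n_cycles + 1) * period
    t_total = n_cycles * period
    times = np.arange(0.0, t_total + 0.5 * sample_interval, sample_interval)
    phase = np.mod(times, period)
    od = od_low * 2.0 ** (phase / tau)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        od = od * rng.lognormal(-sigma**2 / 2.0, sigma, size=od.shape)
    return ODTrace(times=times, od=od, dilution_times=dilutions)
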