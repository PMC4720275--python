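"""Stimulus protocol generation and validation.

A session presents short tone bursts drawn from a 12-element stimulus space
(4 frequencies x 3 stimulation modalities) in pseudo-random order: exact
per-type counts, no immediate repetition of the same stimulus type, and a
silent inter-stimulus interval drawn uniformly from a configurable range.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
import pandas as pd

FREQUENCIES_HZ: tuple[int, ...] = (250, 500, 1000, 2000)
MODALITIES: tuple[str, ...] = ("left", "right", "binaural")

DEFAULT_N_PER_TYPE = 200
DEFAULT_ISI_MIN_MS = 600.0
DEFAULT_ISI_MAX_MS = 800.0
DEFAULT_STIM_DURATION_MS = 200.0


@dataclasses.dataclass(frozen=True, order=True)
class StimulusType:
    """One of the 12 (frequency, modality) stimulus conditions."""

    frequency_hz: int
    modality: str

    def __post_init__(self) -> None:
        if self.frequency_hz not in FREQUENCIES_HZ:
            raise ValueError(f"unknown frequency {self.frequency_hz} Hz")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.frequency_hz}Hz/{self.modality}"


@dataclasses.dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus presentation at ``onset_ms`` from session start."""

    onset_ms: float
    stype: StimulusType


@dataclasses.dataclass
class StimulusProtocol:
    """Ordered stimulus schedule for one recording session.

    ``isi_mode`` states what the inter-stimulus interval means:
    ``"offset"`` (default) is the silence after the burst, so consecutive
    onsets are separated by ``stim_duration_ms + ISI``; ``"onset"`` makes the
    ISI the onset-to-onset gap itself.
    """

    events: list[StimulusEvent]
    seed: int
    n_per_type: int
    isi_min_ms: float
    isi_max_ms: float
    stim_duration_ms: float = DEFAULT_STIM_DURATION_MS
    isi_mode: str = "offset"

    def __len__(self) -> int:
        return len(self.events)

    @property
    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events], dtype=float)

    @property
    def types(self) -> list[StimulusType]:
        return [e.stype for e in self.events]

    def gap_bounds_ms(self) -> tuple[float, float]:
        """Admissible [min, max] onset-to-onset gap implied by the config."""
        if self.isi_mode == "offset":
            return (self.stim_duration_ms + self.isi_min_ms,
                    self.stim_duration_ms + self.isi_max_ms)
        return (self.isi_min_ms, self.isi_max_ms)


@dataclasses.dataclass
class ProtocolValidation:
    """Constraint audit of a protocol: counts, gaps and repeat violations."""

    counts: dict[StimulusType, int]
    min_gap_ms: float
    max_gap_ms: float
    repeat_violations: list[int]
    isi_violations: list[int]
    onset_order_violations: list[int]

    @property
    def n_violations(self) -> int:
        return (len(self.repeat_violations) + len(self.isi_violations)
                + len(self.onset_order_violations))

    @property
    def ok(self) -> bool:
        return self.n_violations == 0


def enumerate_stimulus_types() -> list[StimulusType]:
    """All 12 stimulus types, frequency ascending, modality left/right/binaural."""
    return [StimulusType(f, m) for f in FREQUENCIES_HZ for m in MODALITIES]


def _repair_repeats(order: list[int], rng: np.random.Generator,
                    max_passes: int = 100) -> list[int]:
    """Remove adjacent duplicates from a shuffled type sequence by swapping.

    Each offending position is swapped with the nearest position where both
    ends of the swap remain legal.  Raises if no legal arrangement exists
    (only possible for degenerate inputs, e.g. a single type repeated).
    """
    n = len(order)
    if n <= 1:
        return order

    def ok_at(seq: list[int], i: int) -> bool:
        if i > 0 and seq[i] == seq[i - 1]:
            return False
        if i < n - 1 and seq[i] == seq[i + 1]:
            return False
        return True

    for _ in range(max_passes):
        bad = [i for i in range(1, n) if order[i] == order[i - 1]]
        if not bad:
            return order
        progressed = False
        for i in bad:
            if order[i] != order[i - 1]:
                continue  # fixed by an earlier swap in this pass
            # search outward for the nearest legal swap partner
            for d in range(1, n):
                for j in (i - d, i + d):
                    if j < 0 or j >= n or order[j] == order[i]:
                        continue
                    order[i], order[j] = order[j], order[i]
                    if ok_at(order, i) and ok_at(order, j):
                        progressed = True
                        break
                    order[i], order[j] = order[j], order[i]
                else:
                    continue
                break
        if not progressed:
            # no single swap fixes anything: reshuffle and retry
            perm = rng.permutation(n)
            order = [order[k] for k in perm]
    raise ValueError("no-repeat constraint unsatisfiable for this type multiset")


def generate_protocol(n_per_type: int = DEFAULT_N_PER_TYPE,
                      isi_min_ms: float = DEFAULT_ISI_MIN_MS,
                      isi_max_ms: float = DEFAULT_ISI_MAX_MS,
                      seed: int = 0,
                      stim_duration_ms: float = DEFAULT_STIM_DURATION_MS,
                      isi_mode: str = "offset",
                      start_ms: float = 1000.0,
                      types: list[StimulusType] | None = None) -> StimulusProtocol:
    """Generate a pseudo-random session schedule.

    The multiset of ``12 * n_per_type`` stimulus types is shuffled and adjacent
    repeats are repaired by swapping, which guarantees exact per-type counts
    while satisfying the no-immediate-repeat constraint.  ISIs are drawn
    i.i.d. uniform on ``[isi_min_ms, isi_max_ms]``.

    ``start_ms`` places the first onset away from the recording edge so that
    a prestimulus window can always be extracted.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    if not (0 < isi_min_ms <= isi_max_ms):
        raise ValueError("need 0 < isi_min_ms <= isi_max_ms")
    if isi_mode not in ("offset", "onset"):
        raise ValueError("isi_mode must be 'offset' or 'onset'")

    stypes = list(types) if types is not None else enumerate_stimulus_types()
    if len(set(stypes)) == 1 and n_per_type > 1:
        raise ValueError("no-repeat constraint unsatisfiable: single stimulus type")

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(np.repeat(np.arange(len(stypes)), n_per_type)))
    order = _repair_repeats(order, rng)

    n_events = len(order)
    isis = rng.uniform(isi_min_ms, isi_max_ms, size=n_events - 1) if n_events > 1 else []
    offset = stim_duration_ms if isi_mode == "offset" else 0.0
    onsets = start_ms + np.concatenate([[0.0], np.cumsum(np.asarray(isis) + offset)]) \
        if n_events > 1 else np.array([start_ms])

    events = [StimulusEvent(float(t), stypes[k]) for t, k in zip(onsets, order)]
    return StimulusProtocol(events=events, seed=seed, n_per_type=n_per_type,
                            isi_min_ms=isi_min_ms, isi_max_ms=isi_max_ms,
                            stim_duration_ms=stim_duration_ms, isi_mode=isi_mode)


def validate_protocol(p: StimulusProtocol, tol_ms: float = 1e-9) -> ProtocolValidation:
    """Audit counts, ordering, gap range and the no-repeat constraint."""
    counts: dict[StimulusType, int] = {t: 0 for t in enumerate_stimulus_types()}
    for ev in p.events:
        counts[ev.stype] = counts.get(ev.stype, 0) + 1

    onsets = p.onsets_ms
    gaps = np.diff(onsets)
    lo, hi = p.gap_bounds_ms()

    repeat_violations = [i for i in range(1, len(p.events))
                         if p.events[i].stype == p.events[i - 1].stype]
    isi_violations = [i for i, g in enumerate(gaps, start=1)
                      if g < lo - tol_ms or g > hi + tol_ms]
    order_violations = [i for i, g in enumerate(gaps, start=1) if g <= 0]

    return ProtocolValidation(
        counts=counts,
        min_gap_ms=float(gaps.min()) if len(gaps) else float("nan"),
        max_gap_ms=float(gaps.max()) if len(gaps) else float("nan"),
        repeat_violations=repeat_violations,
        isi_violations=isi_violations,
        onset_order_violations=order_violations,
    )


def protocol_to_csv(p: StimulusProtocol, path: str | Path) -> None:
    """Write the schedule as ``onset_ms,frequency_hz,modality``."""
    df = pd.DataFrame({
        "onset_ms": [e.onset_ms for e in p.events],
        "frequency_hz": [e.stype.frequency_hz for e in p.events],
        "modality": [e.stype.modality for e in p.events],
    })
    df.to_csv(path, index=False, float_format="%.17g")   # lossless round-trip


def events_from_csv(path: str | Path) -> list[StimulusEvent]:
    """Read a ``onset_ms,frequency_hz,modality`` event table."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"onset_ms", "frequency_hz", "modality"}
    if not required.issubset(df.columns):
        raise ValueError(f"event CSV must have columns {sorted(required)}")
    return [StimulusEvent(float(r.onset_ms),
                          StimulusType(int(r.frequency_hz), str(r.modality)))
            for r in df.itertuples(index=False)]


def protocol_from_csv(path: str | Path, **kwargs) -> StimulusProtocol:
    """Rebuild a protocol object from an event CSV.

    Schedule parameters that are not recoverable from the file (seed, ISI
    bounds) may be supplied via keyword arguments; defaults are the session
    defaults.
    """
    events = events_from_csv(path)
    counts = pd.Series([str(e.stype) for e in events]).value_counts()
    n_per_type = int(counts.iloc[0]) if len(counts) else 0
    params = dict(seed=-1, n_per_type=n_per_type,
                  isi_min_ms=DEFAULT_ISI_MIN_MS, isi_max_ms=DEFAULT_ISI_MAX_MS)
    params.update(kwargs)
    return StimulusProtocol(events=events, **params)
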