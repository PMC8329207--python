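"""ERG session records: readers, writers and quality-control exclusion.

One :class:`ERGSession` holds everything measured on one individual under one
adaptation state: the white-flash calibration ladder (flashed before and after
the spectral series) and the per-round monochromatic flash amplitudes.

File dialect (UTF-8, comma-delimited, one header row)::

    individual_id,sex,adaptation,series,round,wavelength_nm,intensity_photons,amplitude_mV

``series`` is one of ``white_before``, ``white_after``, ``mono``.  White rows
leave ``wavelength_nm`` and ``round`` empty; mono rows leave
``intensity_photons`` empty.  Floats are written with ``repr`` so that a
write/read round trip is bit-identical.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ParseError, ValidationError
from .protocol import StimulusProtocol

_HEADER = ["individual_id", "sex", "adaptation", "series", "round",
           "wavelength_nm", "intensity_photons", "amplitude_mV"]
_SEXES = ("male", "female")


@dataclass
class ERGSession:
    """All recordings for one individual under one adaptation state."""

    individual_id: str
    sex: str
    adaptation_label: str
    white_before: list[tuple[float, float]] = field(default_factory=list)
    white_after: list[tuple[float, float]] = field(default_factory=list)
    #: (round index starting at 1, wavelength nm, amplitude mV) in flash order
    mono_responses: list[tuple[int, float, float]] = field(default_factory=list)

    def validate(self, protocol: StimulusProtocol) -> "ERGSession":
        if self.sex not in _SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.adaptation_label not in protocol.adaptation_labels:
            raise ValidationError(
                f"adaptation {self.adaptation_label!r} not in protocol")
        ladder = set(protocol.white_intensities)
        for series in (self.white_before, self.white_after):
            for intensity, amp in series:
                if intensity not in ladder:
                    raise ValidationError(
                        f"white intensity {intensity!r} not on the protocol "
                        f"ladder ({self.individual_id})")
                _check_amplitude(amp, self.individual_id)
        grid = set(protocol.mono_wavelengths)
        seen: dict[tuple[int, float], int] = {}
        for rnd, wl, amp in self.mono_responses:
            if wl not in grid:
                raise ValidationError(
                    f"wavelength {wl} nm not in protocol grid "
                    f"({self.individual_id})")
            _check_amplitude(amp, self.individual_id)
            key = (rnd, wl)
            seen[key] = seen.get(key, 0) + 1
            if seen[key] > 1:
                raise ValidationError(
                    f"duplicate mono flash round={rnd} λ={wl} nm "
                    f"({self.individual_id}/{self.adaptation_label})")
        # mono series must be complete per round (rounds are averaged pairwise)
        rounds = {rnd for rnd, _, _ in self.mono_responses}
        for rnd in rounds:
            got = {wl for r, wl, _ in self.mono_responses if r == rnd}
            if got != grid:
                missing = sorted(grid - got)
                raise ValidationError(
                    f"round {rnd} incomplete: missing λ {missing} "
                    f"({self.individual_id}/{self.adaptation_label})")
        return self


def _check_amplitude(amp: float, who: str) -> None:
    if not math.isfinite(amp) or amp < 0:
        raise ValidationError(
            f"amplitude must be finite and >= 0 mV, got {amp!r} ({who})")


def _fmt(x: float | int | None) -> str:
    return "" if x is None else repr(float(x)) if isinstance(x, float) else str(x)


def write_sessions(sessions: Sequence[ERGSession], path: str | Path) -> None:
    """Write sessions in the canonical dialect (stable order, repr floats)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(_HEADER)
        for s in sessions:
            base = [s.individual_id, s.sex, s.adaptation_label]
            for name, series in (("white_before", s.white_before),
                                 ("white_after", s.white_after)):
                for intensity, amp in series:
                    w.writerow(base + [name, "", "", _fmt(float(intensity)),
                                       _fmt(float(amp))])
            for rnd, wl, amp in s.mono_responses:
                w.writerow(base + ["mono", str(rnd), _fmt(float(wl)), "",
                                   _fmt(float(amp))])


def read_sessions(path: str | Path,
                  protocol: StimulusProtocol) -> list[ERGSession]:
    """Read and validate a session file; row order within sessions preserved."""
    path = Path(path)
    sessions: dict[tuple[str, str], ERGSession] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        if header != _HEADER:
            raise ParseError(f"bad header {header!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_HEADER):
                raise ParseError(f"expected {len(_HEADER)} fields, "
                                 f"got {len(row)}", line=lineno)
            ind, sex, adapt, series, rnd, wl, intensity, amp = row
            key = (ind, adapt)
            sess = sessions.setdefault(
                key, ERGSession(individual_id=ind, sex=sex,
                                adaptation_label=adapt))
            if sess.sex != sex:
                raise ParseError(f"inconsistent sex for {ind!r}", line=lineno)
            try:
                amplitude = float(amp)
            except ValueError:
                raise ParseError(f"bad amplitude {amp!r}", line=lineno) from None
            if series in ("white_before", "white_after"):
                try:
                    inten = float(intensity)
                except ValueError:
                    raise ParseError(f"bad intensity {intensity!r}",
                                     line=lineno) from None
                getattr(sess, series).append((inten, amplitude))
            elif series == "mono":
                try:
                    round_idx = int(rnd)
                    wavelength = float(wl)
                except ValueError:
                    raise ParseError(f"bad mono row {row!r}",
                                     line=lineno) from None
                sess.mono_responses.append((round_idx, wavelength, amplitude))
            else:
                raise ParseError(f"unknown series {series!r}", line=lineno)
    out = list(sessions.values())
    for s in out:
        s.validate(protocol)
    return out


def qc_exclude(sessions: Iterable[ERGSession],
               min_response: float = 0.0,
               ) -> tuple[list[ERGSession], list[str]]:
    """Drop individuals with no depolarisation to the brightest white flash.

    An individual is excluded (all its sessions removed) iff its maximum
    amplitude at the brightest white-ladder intensity, over the before/after
    series of every session, is not strictly greater than ``min_response``
    (default 0 mV: any positive response keeps the individual).
    """
    if min_response < 0:
        raise ValueError("min_response must be >= 0 mV")
    sessions = list(sessions)
    best: dict[str, float] = {}
    for s in sessions:
        whites = list(s.white_before) + list(s.white_after)
        if not whites:
            continue
        brightest = max(i for i, _ in whites)
        peak = max(a for i, a in whites if i == brightest)
        best[s.individual_id] = max(best.get(s.individual_id, 0.0), peak)
    excluded = sorted(ind for ind, peak in best.items()
                      if not peak > min_response)
    kept = [s for s in sessions if s.individual_id not in set(excluded)]
    return kept, excluded
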