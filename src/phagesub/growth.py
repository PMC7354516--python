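"""One-step phage growth-curve analysis.

The 0-min untreated titer represents the number of infected cells and is set
to 1; every other PFU value (including the chloroform-released series, which
measures intracellular phage) is normalized against it. The eclipse period
ends when the chloroform series first exceeds a rise threshold (intracellular
particles appear), the latent period when the untreated series does
(spontaneous lysis); the burst size is the mean normalized titer over the
terminal plateau, and the rise period runs from the end of latency to the
start of that plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class GrowthCurve:
    time: list[float]                       # minutes, strictly increasing
    pfu_untreated: list[float]              # PFU/mL
    pfu_chloroform: list[float] | None = None
    moi: float | None = None

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.time, self.time[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if len(self.pfu_untreated) != len(self.time):
            raise ValueError("untreated series length mismatch")
        if self.pfu_chloroform is not None and len(self.pfu_chloroform) != len(self.time):
            raise ValueError("chloroform series length mismatch")
        if min(self.pfu_untreated) < 0:
            raise ValueError("PFU must be non-negative")
        if 0.0 not in self.time:
            raise ValueError("t=0 sample required in the untreated series")


@dataclass
class GrowthParams:
    eclipse: float | None
    latent: float | None
    rise: float | None
    burst: float | None
    status: str = "ok"
    plateau_start: float | None = None
    notes: list[str] = field(default_factory=list)


def normalize_curve(curve: GrowthCurve) -> GrowthCurve:
    """Divide both series by the untreated 0-min titer (which becomes 1.0)."""
    i0 = curve.time.index(0.0)
    ref = curve.pfu_untreated[i0]
    if ref <= 0:
        raise ValueError("untreated PFU at t=0 must be positive")
    return GrowthCurve(
        list(curve.time),
        [v / ref for v in curve.pfu_untreated],
        None if curve.pfu_chloroform is None else
        [v / ref for v in curve.pfu_chloroform],
        curve.moi,
    )


def _first_crossing(time: list[float], values: list[float], threshold: float) -> float | None:
    for t, v in zip(time, values):
        if v > threshold:
            return t
    return None


def _terminal_plateau(time: list[float], values: list[float], tol: float) -> int | None:
    """Index where the longest terminal run with relative spread <= tol starts
    (>= 2 points required); None when no such run exists."""
    n = len(values)
    for i in range(n - 1):
        tail = values[i:]
        mean = sum(tail) / len(tail)
        if mean <= 0:
            continue
        if (max(tail) - min(tail)) / mean <= tol:
            return i
    return None


def estimate_params(curve: GrowthCurve, rise_threshold: float = 2.0,
                    plateau_tol: float = 0.10) -> GrowthParams:
    """Read eclipse/latent/rise periods and burst size off a normalized curve.

    Requires >= 4 timepoints. A flat curve reports status ``no_rise``; a curve
    without a terminal plateau reports the crossings but no burst.
    """
    if len(curve.time) < 4:
        raise ValueError("need at least 4 timepoints")
    latent = _first_crossing(curve.time, curve.pfu_untreated, rise_threshold)
    eclipse = None
    if curve.pfu_chloroform is not None:
        eclipse = _first_crossing(curve.time, curve.pfu_chloroform, rise_threshold)
    if latent is None:
        return GrowthParams(eclipse, None, None, None, status="no_rise",
                            notes=["untreated series never exceeds rise_threshold"])
    pi = _terminal_plateau(curve.time, curve.pfu_untreated, plateau_tol)
    if pi is None:
        return GrowthParams(eclipse, latent, None, None, status="no_plateau",
                            notes=["no terminal plateau within tolerance"])
    plateau_start = curve.time[pi]
    tail = curve.pfu_untreated[pi:]
    burst = sum(tail) / len(tail)
    rise = plateau_start - latent
    return GrowthParams(eclipse, latent, rise, burst, status="ok",
                        plateau_start=plateau_start)
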