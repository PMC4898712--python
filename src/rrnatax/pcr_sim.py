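"""Mock-community PCR-bias and qPCR quantification simulator.

Models the classic amplification-bias experiment: a defined mixture of
cloned 16S rRNA genes (known copy-number ratios) is amplified for a fixed
number of cycles, each template with its own per-cycle efficiency
``e_i`` (the probability that a molecule duplicates in one cycle), and
the resulting pool is quantified against six-point ten-fold standard
curves relating Ct to log10 template copies.

Deterministic amplification follows the closed form
``copies(n) = copies(0) * (1 + e)**n``; the stochastic mode duplicates
each molecule independently (binomial per cycle), which matters at low
copy number.  Efficiency is constant across cycles — no plateau term —
because bias ratios are interpreted at fixed cycle counts; a saturation
model would add parameters nothing here constrains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CloneTemplate",
    "AmplificationModel",
    "StandardCurve",
    "amplify",
    "dilution_series",
    "ct_from_copies",
    "fit_standard_curve",
    "quantify",
    "normalize_ratio",
]


@dataclass
class CloneTemplate:
    """A cloned 16S rRNA gene in the mock community."""

    id: str
    copies: float
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.copies <= 0:
            raise ValueError(f"template {self.id!r}: copies must be positive")


@dataclass
class AmplificationModel:
    """Per-template per-cycle duplication efficiencies and a cycle count."""

    efficiencies: dict[str, float]
    cycles: int
    mode: str = "deterministic"  # deterministic | stochastic
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycle count must be >= 0")
        for tid, e in self.efficiencies.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficiency for {tid!r} must be in [0, 1], got {e}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class StandardCurve:
    """Linear model Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float = 1.0

    @property
    def efficiency_percent(self) -> float:
        """(10**(-1/slope) - 1) * 100; 100% means perfect doubling."""
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0

    @property
    def is_valid(self) -> bool:
        return self.slope < 0


def amplify(
    templates: Sequence[CloneTemplate], model: AmplificationModel
) -> list[CloneTemplate]:
    """Amplify each template over ``model.cycles`` PCR cycles.

    Deterministic mode applies ``copies * (1 + e)**n`` exactly.
    Stochastic mode draws, per cycle, Binomial(molecules, e) new
    molecules, seeded from ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    out = []
    for tpl in templates:
        if tpl.id not in model.efficiencies:
            raise KeyError(f"no efficiency for template {tpl.id!r}")
        e = model.efficiencies[tpl.id]
        if model.mode == "deterministic":
            final = tpl.copies * (1.0 + e) ** model.cycles
        else:
            molecules = int(round(tpl.copies))
            for _ in range(model.cycles):
                molecules += int(rng.binomial(molecules, e))
            final = float(molecules)
        out.append(replace(tpl, copies=final))
    return out


def dilution_series(high: float, low: float, fold: float = 10.0) -> list[float]:
    """Descending geometric dilution series from ``high`` to ``low`` inclusive.

    ``low`` must be reachable from ``high`` by an integer number of
    ``fold``-steps (e.g. 1e8 -> 1e3 by tenfold steps gives six points).
    """
    if high <= 0 or low <= 0:
        raise ValueError("copy numbers must be positive")
    if high < low:
        raise ValueError("high must be >= low")
    if fold <= 1:
        raise ValueError("fold must be > 1")
    n_steps = math.log(high / low) / math.log(fold)
    steps = round(n_steps)
    if abs(n_steps - steps) > 1e-9:
        raise ValueError(
            f"{low} is not reachable from {high} by integer {fold}-fold steps"
        )
    return [high / fold**i for i in range(steps + 1)]


def ct_from_copies(
    copies: float,
    curve: StandardCurve,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> float:
    """Simulated instrument read-out: Ct from template copies.

    Gaussian replicate noise of SD ``noise_sd`` cycles is added when
    requested; ``noise_sd=0`` is exactly the curve value.
    """
    if copies <= 0:
        raise ValueError("copies must be positive")
    ct = curve.intercept + curve.slope * math.log10(copies)
    if noise_sd > 0:
        ct += float(np.random.default_rng(seed).normal(0.0, noise_sd))
    return ct


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) from (copies, Ct) points.

    Requires at least two distinct copy levels.  A non-negative slope is
    physically invalid (more template cannot raise Ct) and is rejected.
    """
    if len(points) < 2:
        raise ValueError("need at least two standard points")
    log_copies = [math.log10(c) for c, _ in points]
    cts = [ct for _, ct in points]
    if len(set(log_copies)) < 2:
        raise ValueError("need at least two distinct copy levels")
    fit = stats.linregress(log_copies, cts)
    slope, intercept = float(fit.slope), float(fit.intercept)
    if slope >= 0:
        raise ValueError(f"invalid standard curve: slope {slope} is not negative")
    return StandardCurve(slope=slope, intercept=intercept, r_squared=float(fit.rvalue) ** 2)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Absolute quantification: copies = 10**((ct - intercept) / slope)."""
    if not curve.is_valid:
        raise ValueError("cannot quantify against a curve with non-negative slope")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalize_ratio(copies: Sequence[float]) -> list[float]:
    """Express copy numbers relative to the smallest (minimum maps to 1)."""
    if not copies:
        raise ValueError("empty copy list")
    if min(copies) <= 0:
        raise ValueError("all copy numbers must be positive")
    low = min(copies)
    return [c / low for c in copies]
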