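"""Weight-based intravenous dosing schedules.

Three named presets mirror the simulated regimens:

* ``smpc``       - LD 6 mg/kg q12h x2, then MD 4 mg/kg q12h (label dosing);
* ``escalate-6`` - LD 6 mg/kg q12h x2, MD 4 mg/kg x8, then 6 mg/kg q12h;
* ``escalate-8`` - LD 8 mg/kg q12h x2, MD 6 mg/kg x8, then 8 mg/kg q12h.

Doses are placed every ``interval`` hours starting at t = 0; events whose
start time reaches the simulation horizon are not scheduled.  Amounts are
mg/kg times the dosing weight, rounded to whole mg.  For obese patients
(actual weight more than 20% above ideal body weight) the dosing weight is
the adjusted body weight ABW = IBW + 0.4 * (actual - IBW), with IBW from
the Devine formula.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model_core import DoseEvent

__all__ = [
    "Phase",
    "RegimenSpec",
    "PRESETS",
    "get_preset",
    "ideal_body_weight",
    "dosing_weight",
    "build_regimen",
]


@dataclass(frozen=True)
class Phase:
    """A run of identical doses: mg/kg and how many (None = open-ended)."""

    mg_per_kg: float
    n_doses: int | None = None

    def __post_init__(self) -> None:
        if self.mg_per_kg <= 0:
            raise ValueError("mg_per_kg must be > 0")
        if self.n_doses is not None and self.n_doses < 1:
            raise ValueError("n_doses must be >= 1 or None")


@dataclass(frozen=True)
class RegimenSpec:
    """Ordered dosing phases with a common interval and infusion duration."""

    phases: tuple[Phase, ...]
    interval: float = 12.0
    infusion_duration: float = 2.0
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("regimen must have at least one phase")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.infusion_duration <= 0:
            raise ValueError("infusion duration must be > 0")
        for ph in self.phases[:-1]:
            if ph.n_doses is None:
                raise ValueError("only the last phase may be open-ended")


def _preset(name: str, *phases) -> RegimenSpec:
    return RegimenSpec(tuple(Phase(*p) for p in phases), name=name)


PRESETS: dict[str, RegimenSpec] = {
    "smpc": _preset("smpc", (6.0, 2), (4.0, None)),
    "escalate-6": _preset("escalate-6", (6.0, 2), (4.0, 8), (6.0, None)),
    "escalate-8": _preset("escalate-8", (8.0, 2), (6.0, 8), (8.0, None)),
}


def get_preset(name: str) -> RegimenSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown regimen preset {name!r}; available: "
            f"{', '.join(sorted(PRESETS))}") from None


def ideal_body_weight(height_cm: float, sex: str) -> float:
    """Devine ideal body weight: 50 kg (M) / 45.5 kg (F) + 2.3 kg per inch over 5 ft."""
    if height_cm <= 0:
        raise ValueError("height must be > 0")
    base = {"M": 50.0, "F": 45.5}.get(str(sex).upper()[:1])
    if base is None:
        raise ValueError("sex must be 'M' or 'F'")
    inches_over = max(height_cm / 2.54 - 60.0, 0.0)
    return base + 2.3 * inches_over


def dosing_weight(weight: float, height_cm: float | None = None,
                  sex: str | None = None,
                  screening_threshold: float = 100.0) -> float:
    """Weight used for mg/kg dosing.

    Returns the actual weight unless it exceeds 1.2x the Devine ideal body
    weight, in which case the adjusted body weight IBW + 0.4*(actual - IBW)
    is returned.  Height (and sex) are required only when the obesity rule
    could plausibly trigger, i.e. when actual weight exceeds
    ``screening_threshold`` kg.
    """
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if height_cm is None or sex is None:
        if weight > screening_threshold:
            raise ValueError(
                f"height and sex required to evaluate the obesity rule for "
                f"weight {weight} kg (> screening threshold "
                f"{screening_threshold} kg)")
        return weight
    ibw = ideal_body_weight(height_cm, sex)
    if weight > 1.2 * ibw:
        return ibw + 0.4 * (weight - ibw)
    return weight


def build_regimen(spec: RegimenSpec, dosing_weight_kg: float,
                  horizon: float) -> list[DoseEvent]:
    """Expand a regimen into timed dose events for one subject.

    Doses start at 0, ``interval``, 2*``interval``, ... strictly before the
    horizon; amounts are rounded to whole mg.
    """
    if dosing_weight_kg <= 0:
        raise ValueError("dosing weight must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    events: list[DoseEvent] = []
    t = 0.0
    for phase in spec.phases:
        n = phase.n_doses if phase.n_doses is not None else int(1e9)
        amount = round(phase.mg_per_kg * dosing_weight_kg)
        for _ in range(n):
            if t >= horizon:
                return events
            events.append(DoseEvent(start_time=t, amount=float(amount),
                                    duration=spec.infusion_duration))
            t += spec.interval
    return events
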