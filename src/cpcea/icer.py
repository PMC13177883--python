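"""Incremental cost-effectiveness ratios and dominance classification.

The ICER compares an intervention against a comparator on the cost-effectiveness
plane: ``ICER = delta_cost / delta_effect`` (EUR per QALY).  The quadrant of
(delta_effect, delta_cost) determines how the ratio is read:

* northeast (more effective, more costly) -- the ordinary trade-off; report the
  ratio and judge it against a willingness-to-pay threshold;
* "dominated" (less effective, more costly) -- the intervention is worse on both
  axes, no ratio is reported;
* "dominant" (more effective, less costly) -- the intervention wins on both axes;
* southwest (less effective, less costly) -- the ratio is reported with an
  explicit flag, because its interpretation inverts (it is the saving per QALY
  forgone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UndefinedRatioError

#: Default tolerance below which |delta_effect| is treated as zero QALYs.
EFFECT_TOLERANCE = 1e-6


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison of one therapy/strategy against a comparator."""

    therapy: str
    delta_cost: float
    delta_effect: float
    classification: str  # one of {"icer", "dominated", "dominant"}
    icer_value: float | None = None
    southwest: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.classification not in {"icer", "dominated", "dominant"}:
            raise ValueError(f"unknown classification {self.classification!r}")
        if (self.icer_value is not None) != (self.classification == "icer"):
            raise ValueError("icer_value must be present iff classification == 'icer'")

    @property
    def label(self) -> str:
        """Human-readable cell for a results table."""
        if self.classification == "dominated":
            return "Dominated"
        if self.classification == "dominant":
            return "Dominant"
        assert self.icer_value is not None
        suffix = " (SW)" if self.southwest else ""
        return f"{self.icer_value:,.0f} EUR/QALY{suffix}"


def classify_icer(
    therapy: str,
    delta_cost: float,
    delta_effect: float,
    effect_tolerance: float = EFFECT_TOLERANCE,
) -> IcerResult:
    """Classify an incremental (cost, effect) pair and form the ratio if defined.

    Parameters
    ----------
    therapy
        Label carried through to the result.
    delta_cost, delta_effect
        Incremental cost (EUR) and effect (QALY) versus the comparator.
    effect_tolerance
        |delta_effect| below this raises :class:`UndefinedRatioError` instead of
        producing an exploding ratio from numerical noise.
    """
    if abs(delta_effect) < effect_tolerance:
        raise UndefinedRatioError(
            f"{therapy}: |delta_effect| = {abs(delta_effect):.3g} QALY is below the "
            f"tolerance {effect_tolerance:g}; the ICER is undefined"
        )
    if delta_effect < 0 and delta_cost > 0:
        return IcerResult(therapy, delta_cost, delta_effect, "dominated")
    if delta_effect > 0 and delta_cost < 0:
        return IcerResult(therapy, delta_cost, delta_effect, "dominant")
    southwest = delta_effect < 0 and delta_cost <= 0
    return IcerResult(
        therapy,
        delta_cost,
        delta_effect,
        "icer",
        icer_value=delta_cost / delta_effect,
        southwest=southwest,
    )
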