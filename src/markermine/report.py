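"""Summary arithmetic and the machine-readable pipeline report.

All printed percentages and ratios use round-half-up (not banker's
rounding), and every percentage in a :class:`SummaryReport` is stored next
to its numerator and denominator so it can be recomputed by the reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from numbers import Integral
from pathlib import Path


def round_half_up(x: float | Decimal, decimals: int = 0) -> float:
    """Round with ties away from zero at ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    d = x if isinstance(x, Decimal) else Decimal(repr(float(x)))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, decimals: int = 0) -> float | int:
    """Round-half-up percentage; exact rational arithmetic before rounding."""
    if denominator < 1:
        raise ValueError("percent: denominator must be >= 1")
    if numerator < 0:
        raise ValueError("percent: numerator must be >= 0")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    rounded = round_half_up(value, decimals)
    return int(rounded) if decimals == 0 else rounded


def ratio(numerator: float, denominator: int, decimals: int = 0) -> float | int:
    """Round-half-up ratio of a quantity to a count."""
    if denominator < 1:
        raise ValueError("ratio: denominator must be >= 1")
    if isinstance(numerator, Integral):
        value = Decimal(int(numerator)) / Decimal(denominator)
    else:
        value = Decimal(repr(float(numerator))) / Decimal(denominator)
    rounded = round_half_up(value, decimals)
    return int(rounded) if decimals == 0 else rounded


@dataclass
class SummaryReport:
    """Headline counts and rates of one pipeline run.

    Percentages carry their numerator/denominator beside them (as the
    ``counts`` dict) so every printed figure is auditable.
    """

    counts: dict[str, int] = field(default_factory=dict)
    percents: dict[str, float] = field(default_factory=dict)
    ratios: dict[str, float] = field(default_factory=dict)
    distributions: dict[str, dict] = field(default_factory=dict)

    def add_percent(self, name: str, numerator: int, denominator: int, decimals: int = 0) -> None:
        self.counts[f"{name}_num"] = numerator
        self.counts[f"{name}_den"] = denominator
        self.percents[name] = percent(numerator, denominator, decimals) if denominator else None

    def as_flat_dict(self) -> dict[str, object]:
        flat: dict[str, object] = {}
        for k, v in self.counts.items():
            flat[f"count.{k}"] = v
        for k, v in self.percents.items():
            flat[f"percent.{k}"] = v
        for k, v in self.ratios.items():
            flat[f"ratio.{k}"] = v
        for name, dist in self.distributions.items():
            for k, v in dist.items():
                flat[f"{name}.{k}"] = v
        return flat

    def write_key_value(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in self.as_flat_dict().items():
                fh.write(f"{k}\t{v}\n")
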