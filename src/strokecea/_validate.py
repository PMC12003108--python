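"""Shared validation helpers and exception types."""

from __future__ import annotations


class ConfigurationError(KeyError):
    """A required configuration key is missing."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


def check_probability(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a probability in [0, 1], got {value}")
    return value


def check_nonnegative(name: str, value: float) -> float:
    value = float(value)
    if value < 0.0:
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


def check_positive(name: str, value: float) -> float:
    value = float(value)
    if value <= 0.0:
        raise ValidationError(f"{name} must be strictly positive, got {value}")
    return value


def check_range(name: str, low: float, point: float, high: float) -> None:
    if not low <= point <= high:
        raise ValidationError(
            f"{name}: range must bracket the point value, got low={low}, point={point}, high={high}"
        )
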