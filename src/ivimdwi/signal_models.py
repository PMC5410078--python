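"""Forward signal models for multi-b-value diffusion-weighted MRI.

Three representations of the per-voxel signal decay ``S(b)`` are used
throughout the package:

* a two-point apparent diffusion coefficient ``ADC_b`` computed from the
  b=0 volume and a single non-zero b,
* a monoexponential decay ``S(b) = S0 * exp(-b * ADC_total)`` fitted over
  all b-values, and
* the biexponential intravoxel incoherent motion (IVIM) model
  ``S(b) = S0 * (f * exp(-b * ADC_fast) + (1 - f) * exp(-b * ADC_slow))``
  which splits the decay into a perfusion (pseudo-diffusion) compartment
  with volume fraction ``f`` and a tissue-diffusion compartment.

All diffusion coefficients are stored in mm^2/s.  Reporting layers
multiply by 1e3 to obtain the conventional "x10^-3 mm^2/s" scale; the
conversion never happens silently inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BValueScheme",
    "MonoexpParams",
    "IVIMParams",
    "STUDY_B_VALUES",
    "monoexp_signal",
    "biexp_signal",
    "two_point_adc",
]

#: Diffusion weightings (s/mm^2) of the nine-point acquisition scheme the
#: package defaults emulate.
STUDY_B_VALUES = (0.0, 20.0, 50.0, 100.0, 200.0, 400.0, 600.0, 800.0, 1000.0)


@dataclass(frozen=True)
class BValueScheme:
    """Ordered list of diffusion weightings, s/mm^2.

    Invariants: the first value is 0, values are strictly increasing and
    non-negative, and at least two values are present.
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("b-value scheme needs at least two values")
        if vals[0] != 0.0:
            raise ValueError("b-value scheme must start at b=0")
        arr = np.asarray(vals)
        if np.any(arr < 0):
            raise ValueError("b-values must be non-negative")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("b-values must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def nonzero(self) -> np.ndarray:
        return self.array[1:]

    @classmethod
    def study_scheme(cls) -> "BValueScheme":
        """The default nine-b-value scheme (0 to 1000 s/mm^2)."""
        return cls(STUDY_B_VALUES)


@dataclass(frozen=True)
class MonoexpParams:
    """Monoexponential decay parameters: amplitude and ADC_total (mm^2/s)."""

    s0: float
    adc_total: float

    def validate(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")
        if not self.adc_total > 0:
            raise ValueError(f"adc_total must be positive, got {self.adc_total}")


@dataclass(frozen=True)
class IVIMParams:
    """Biexponential IVIM parameters.

    Attributes
    ----------
    s0 : float
        Non-weighted signal amplitude, arbitrary units.
    f : float
        Perfusion fraction, dimensionless in [0, 1].
    adc_slow : float
        Tissue diffusion coefficient (D), mm^2/s.
    adc_fast : float
        Pseudo-diffusion coefficient (D*), mm^2/s.
    """

    s0: float
    f: float
    adc_slow: float
    adc_fast: float

    def validate(self, strict_order: bool = True) -> None:
        """Check the parameter invariants.

        With ``strict_order`` (the fit-output contract) ``adc_slow`` must be
        strictly smaller than ``adc_fast``; forward evaluation tolerates
        equality, so generators may pass ``strict_order=False``.
        """
        if not self.s0 > 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if not self.adc_slow > 0:
            raise ValueError(f"adc_slow must be positive, got {self.adc_slow}")
        if strict_order:
            if not self.adc_slow < self.adc_fast:
                raise ValueError(
                    "adc_slow must be smaller than adc_fast, got "
                    f"{self.adc_slow} >= {self.adc_fast}"
                )
        elif self.adc_fast < self.adc_slow:
            raise ValueError("adc_fast must not be smaller than adc_slow")

    def as_array(self) -> np.ndarray:
        return np.array([self.s0, self.f, self.adc_slow, self.adc_fast])


def _check_b(b) -> np.ndarray:
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    return b


def monoexp_signal(params: MonoexpParams, b) -> np.ndarray | float:
    """Evaluate the monoexponential decay ``s0 * exp(-b * adc_total)``.

    ``b`` may be scalar or array-like (s/mm^2); negative b is rejected.
    """
    barr = _check_b(b)
    out = params.s0 * np.exp(-barr * params.adc_total)
    return float(out) if np.isscalar(b) or barr.ndim == 0 else out


def biexp_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Evaluate the IVIM biexponential decay at weighting(s) ``b``.

    Returns ``s0 * (f * exp(-b*adc_fast) + (1-f) * exp(-b*adc_slow))``;
    equals ``s0`` at b=0 and reduces to the monoexponential model when
    ``f`` is 0 or 1.
    """
    barr = _check_b(b)
    out = params.s0 * (
        params.f * np.exp(-barr * params.adc_fast)
        + (1.0 - params.f) * np.exp(-barr * params.adc_slow)
    )
    return float(out) if np.isscalar(b) or barr.ndim == 0 else out


def two_point_adc(s0, sb, b) -> float | np.ndarray:
    """Two-point ADC: ``(1/b) * ln(s0 / sb)`` in mm^2/s.

    Requires ``b > 0`` and strictly positive signals.  The result is 0
    when ``sb == s0`` and may be negative when noise pushes ``sb`` above
    ``s0``; callers that need quality flags handle the sign downstream
    (values are never clamped here).

    Raises
    ------
    ValueError
        If ``b`` is not strictly positive, or any signal is non-positive.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("two-point ADC requires a strictly positive b-value")
    s0a = np.asarray(s0, dtype=float)
    sba = np.asarray(sb, dtype=float)
    if np.any(s0a <= 0) or np.any(sba <= 0):
        raise ValueError("two-point ADC requires strictly positive signals")
    out = np.log(s0a / sba) / b
    if np.isscalar(s0) and np.isscalar(sb) and out.ndim == 0:
        return float(out)
    return out
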