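"""Thin-elastic-sheet wrinkle mechanics for adsorption layers.

A compressed elastic surface layer of thickness h buckles into wrinkles whose
wavelength is set by its flexural rigidity D, the surface tension σ and the
sheet length L:

    λ = 2 √π (D/σ)^(1/4) L^(1/2)

The rigidity follows from the interfacial (2D) moduli measured in surface
rheology: the Poisson ratio ν = G'_D / (2 G'_S) − 1, the 2D Young's modulus
Y_s = 2 G'_S (1 + ν) (algebraically identical to G'_D), the pseudo-bulk
Young's modulus Y = Y_s / h, and

    D = Y h³ / (1 − ν²).

The rigidity expression is used in the divided form, without the classical
plate-theory factor 1/12; pass ``classical_plate=True`` to
:func:`flexural_rigidity` to include it for comparison with textbook plates.
All functions are SI; convenience nm input is accepted for h.  No
intermediate rounding is performed anywhere in the chain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .constants import DEFAULT_TEMPERATURE, K_B
from .errors import ParameterError


@dataclass(frozen=True)
class ElasticSheetParams:
    """Inputs of the wrinkle-mechanics chain (SI units).

    ``sigma`` (surface tension, N/m) and ``L`` (sheet length, m) are only
    needed when a wrinkle wavelength is requested.
    """

    G_S: float  # interfacial shear modulus, N/m
    G_D: float  # interfacial dilatational modulus, N/m
    h: float  # layer thickness, m
    sigma: float | None = None  # N/m
    L: float | None = None  # m
    T: float = DEFAULT_TEMPERATURE  # K

    def __post_init__(self) -> None:
        if self.G_S <= 0 or self.G_D <= 0:
            raise ParameterError("interfacial moduli must be positive")
        if self.h <= 0:
            raise ParameterError("layer thickness must be positive")
        if self.T <= 0:
            raise ParameterError("temperature must be positive")
        if (self.sigma is not None and self.sigma <= 0) or (
            self.L is not None and self.L <= 0
        ):
            raise ParameterError("sigma and L must be positive when given")

    @classmethod
    def with_h_nm(cls, G_S: float, G_D: float, h_nm: float, **kw
                  ) -> "ElasticSheetParams":
        return cls(G_S=G_S, G_D=G_D, h=h_nm * 1e-9, **kw)


@dataclass(frozen=True)
class ElasticResults:
    nu: float  # Poisson's ratio
    Ys: float  # 2D Young's modulus, N/m
    Y: float  # pseudo-bulk Young's modulus, Pa
    D: float  # flexural rigidity, J
    D_kBT: float  # D / (k_B T)
    wavelength: float | None  # m, when sigma and L were given


def poisson_ratio(G_D: float, G_S: float) -> float:
    """ν = G'_D / (2 G'_S) − 1 from the interfacial moduli."""
    if G_S <= 0:
        raise ParameterError("shear modulus must be positive")
    nu = G_D / (2.0 * G_S) - 1.0
    if not 0.0 < nu < 0.5:
        warnings.warn(
            f"Poisson ratio {nu:.3f} outside (0, 0.5); physically unusual "
            "for this sheet model",
            stacklevel=2,
        )
    return nu


def young_modulus_2d(G_S: float, nu: float) -> float:
    """2D Young's modulus Y_s = 2 G'_S (1 + ν), in N/m."""
    return 2.0 * G_S * (1.0 + nu)


def young_modulus_bulk(Ys: float, h: float) -> float:
    """Pseudo-bulk Young's modulus Y = Y_s / h, in Pa (h in m)."""
    if h <= 0:
        raise ParameterError("thickness must be positive")
    return Ys / h


def flexural_rigidity(
    Y: float, h: float, nu: float, classical_plate: bool = False
) -> float:
    """Flexural rigidity D = Y h³ / (1 − ν²), in J (Y in Pa, h in m).

    ``classical_plate`` adds the 1/12 factor of classical plate theory.
    """
    if abs(nu) >= 1:
        raise ParameterError("|nu| must be < 1")
    d = Y * h**3 / (1.0 - nu**2)
    return d / 12.0 if classical_plate else d


def rigidity_in_kBT(D: float, T: float) -> float:
    """Flexural rigidity in thermal-energy units, D / (k_B T)."""
    if T <= 0:
        raise ParameterError("temperature must be positive")
    return D / (K_B * T)


def wrinkle_wavelength(D: float, sigma: float, L: float) -> float:
    """λ = 2 √π (D/σ)^(1/4) L^(1/2); D in J, σ in N/m, L in m → λ in m."""
    if sigma <= 0 or L <= 0:
        raise ParameterError("sigma and L must be positive")
    return 2.0 * math.sqrt(math.pi) * (D / sigma) ** 0.25 * math.sqrt(L)


def elastic_chain(params: ElasticSheetParams,
                  classical_plate: bool = False) -> ElasticResults:
    """Compose the full chain without intermediate rounding."""
    nu = poisson_ratio(params.G_D, params.G_S)
    ys = young_modulus_2d(params.G_S, nu)
    y = young_modulus_bulk(ys, params.h)
    d = flexural_rigidity(y, params.h, nu, classical_plate)
    lam = None
    if params.sigma is not None and params.L is not None:
        lam = wrinkle_wavelength(d, params.sigma, params.L)
    return ElasticResults(
        nu=nu, Ys=ys, Y=y, D=d,
        D_kBT=rigidity_in_kBT(d, params.T),
        wavelength=lam,
    )
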