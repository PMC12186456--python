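"""Cell sizing and biovolume-to-carbon conversion.

Every biomass quantity in the package funnels through allometric carbon
models of the form ``C = scale * V**exponent`` (C in pg, V in µm³).
Separate models are kept for prey and predator because the two organisms
follow different allometries: the defaults correspond to a cryptophyte
flagellate prey (mean cell volume 221 µm³, ≈27 pg C cell⁻¹) and an
oligotrich ciliate predator (mean cell volume 63,650 µm³, ≈7.00 ng C
cell⁻¹).

Cell volumes enter either directly (electronic particle counter) or from
length × width measurements assuming a prolate spheroid rotated about
the long axis, the standard protistological convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CarbonModel",
    "CellMorphometry",
    "DimensionError",
    "PREY_CARBON",
    "PREDATOR_CARBON",
    "PREY_CELL_VOLUME",
    "PREDATOR_CELL_VOLUME",
    "spheroid_volume",
    "carbon_from_volume",
    "biomass_concentration",
    "round_sig",
]


class DimensionError(ValueError):
    """Raised for physically impossible cell dimensions or densities."""


@dataclass(frozen=True)
class CarbonModel:
    """Allometric carbon content model ``C = scale * V**exponent``.

    Parameters
    ----------
    scale : float
        Prefactor in pg C per µm³^exponent; must be positive.
    exponent : float
        Dimensionless allometric exponent in ``(0, 1.2]``.
    organism_label : str
        Free-text label of the organism the coefficients were fitted for.
    """

    scale: float
    exponent: float
    organism_label: str = ""

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"carbon model scale must be > 0, got {self.scale}")
        if not 0 < self.exponent <= 1.2:
            raise ValueError(
                f"carbon model exponent must lie in (0, 1.2], got {self.exponent}"
            )

    def carbon_pg(self, volume_um3: float) -> float:
        """Per-cell carbon content (pg C) for a cell of ``volume_um3`` µm³."""
        return carbon_from_volume(volume_um3, self)


#: Cryptophyte (prey) carbon allometry, pg C = 0.261 · V^0.860.
PREY_CARBON = CarbonModel(0.261, 0.860, organism_label="cryptophyte prey")
#: Oligotrich ciliate (predator) carbon allometry, pg C = 0.216 · V^0.939.
PREDATOR_CARBON = CarbonModel(0.216, 0.939, organism_label="ciliate predator")

#: Mean prey cell volume (µm³), measured by electronic particle counter.
PREY_CELL_VOLUME = 221.0
#: Mean predator cell volume (µm³), from length × width imaging.
PREDATOR_CELL_VOLUME = 63_650.0


@dataclass(frozen=True)
class CellMorphometry:
    """Summary morphometry of a measured cell population.

    ``volume_um3`` may be measured directly by an instrument (leave
    ``length_um``/``width_um`` as ``None``) or derived from linear
    dimensions via :func:`spheroid_volume`.
    """

    volume_um3: float
    length_um: float | None = None
    width_um: float | None = None
    n_measured: int = 0

    def __post_init__(self) -> None:
        if not self.volume_um3 > 0:
            raise DimensionError(f"cell volume must be > 0, got {self.volume_um3}")
        if (self.length_um is None) != (self.width_um is None):
            raise DimensionError("length and width must be given together")
        if self.length_um is not None:
            _check_dimensions(self.length_um, self.width_um)

    @classmethod
    def from_dimensions(
        cls, length_um: float, width_um: float, n_measured: int = 0
    ) -> "CellMorphometry":
        """Build from length × width, deriving the prolate-spheroid volume."""
        return cls(
            volume_um3=spheroid_volume(length_um, width_um),
            length_um=length_um,
            width_um=width_um,
            n_measured=n_measured,
        )

    @classmethod
    def from_volume(cls, volume_um3: float, n_measured: int = 0) -> "CellMorphometry":
        """Build from an instrument-measured volume (no linear dimensions)."""
        return cls(volume_um3=volume_um3, n_measured=n_measured)


def _check_dimensions(length_um: float, width_um: float) -> None:
    if not (width_um > 0 and length_um > 0):
        raise DimensionError(
            f"cell dimensions must be positive, got length={length_um}, width={width_um}"
        )
    if length_um < width_um:
        raise DimensionError(
            f"length must be >= width for a prolate spheroid, got "
            f"length={length_um} < width={width_um}"
        )


def spheroid_volume(length_um: float, width_um: float) -> float:
    """Volume (µm³) of a prolate spheroid with axes ``length × width × width``.

    V = (π/6) · L · W², the spheroid rotated about its long axis. A sphere
    is the ``length == width`` limit, V = πd³/6.
    """
    _check_dimensions(length_um, width_um)
    return math.pi / 6.0 * length_um * width_um**2


def carbon_from_volume(volume_um3, model: CarbonModel):
    """Per-cell carbon content (pg C) from cell volume (µm³).

    Accepts scalars or arrays; divide by 1000 for ng C.
    """
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v <= 0):
        raise DimensionError("cell volume must be > 0")
    out = model.scale * v**model.exponent
    return float(out) if np.isscalar(volume_um3) else out


def biomass_concentration(density_per_ml, carbon_per_cell_pg: float):
    """Biomass concentration (mg C L⁻¹) from cell density and per-cell carbon.

    pg C mL⁻¹ → mg C L⁻¹ is a factor 10⁻⁶ (10³ mL per L, 10⁻⁹ mg per pg).
    """
    d = np.asarray(density_per_ml, dtype=float)
    if np.any(d < 0):
        raise DimensionError("cell density must be >= 0")
    out = d * carbon_per_cell_pg * 1e-6
    return float(out) if np.isscalar(density_per_ml) else out


def round_sig(x: float, sig: int = 2) -> float:
    """Round ``x`` to ``sig`` significant figures (reporting helper)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def read_morphometry_csv(path) -> dict[str, CellMorphometry]:
    """Read a morphometry table keyed by organism label.

    Columns: ``organism,label,length_um,width_um,volume_um3,n``.  Either
    the linear dimensions or the volume must be present per row; when
    only dimensions are given the spheroid volume is derived.
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"organism", "label", "length_um", "width_um", "volume_um3", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphometry table missing columns: {sorted(missing)}")
    out: dict[str, CellMorphometry] = {}
    for _, row in df.iterrows():
        key = str(row["organism"])
        n = int(row["n"]) if not pd.isna(row["n"]) else 0
        if not pd.isna(row["volume_um3"]):
            length = None if pd.isna(row["length_um"]) else float(row["length_um"])
            width = None if pd.isna(row["width_um"]) else float(row["width_um"])
            out[key] = CellMorphometry(
                volume_um3=float(row["volume_um3"]),
                length_um=length,
                width_um=width,
                n_measured=n,
            )
        elif not (pd.isna(row["length_um"]) or pd.isna(row["width_um"])):
            out[key] = CellMorphometry.from_dimensions(
                float(row["length_um"]), float(row["width_um"]), n_measured=n
            )
        else:
            raise ValueError(
                f"morphometry row for {key!r} needs a volume or both dimensions"
            )
    return out
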