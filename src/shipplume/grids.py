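"""Fixed sectional diameter grid.

The particle population is discretized on a fixed, logarithmically spaced
grid of diameter sections. Sections never move: condensation and coagulation
move number and mass *between* sections, which is numerically robust for
continuous nucleation at the small-diameter end of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SizeGrid"]


@dataclass(frozen=True)
class SizeGrid:
    """Log-spaced diameter sections spanning ``d_min_nm`` to ``d_max_nm``.

    Parameters
    ----------
    n_sections:
        Number of sections (default 120).
    d_min_nm, d_max_nm:
        Grid bounds in nm. The default lower bound of 1 nm keeps freshly
        nucleated clusters (~1.5 nm) on the grid; the upper bound of
        10 µm covers the coarse tail of the exhaust distribution.
    """

    n_sections: int = 120
    d_min_nm: float = 1.0
    d_max_nm: float = 1.0e4

    edges_nm: np.ndarray = field(init=False, repr=False, compare=False)
    centers_nm: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_sections < 2:
            raise ValueError("need at least 2 sections")
        if not 0.0 < self.d_min_nm < self.d_max_nm:
            raise ValueError("require 0 < d_min_nm < d_max_nm")
        edges = np.logspace(
            np.log10(self.d_min_nm), np.log10(self.d_max_nm), self.n_sections + 1
        )
        object.__setattr__(self, "edges_nm", edges)
        object.__setattr__(self, "centers_nm", np.sqrt(edges[:-1] * edges[1:]))

    # -- derived geometry ---------------------------------------------------
    @property
    def centers_m(self) -> np.ndarray:
        return self.centers_nm * 1e-9

    @property
    def volumes_cm3(self) -> np.ndarray:
        """Single-particle volume at section centers (cm^3)."""
        d_cm = self.centers_nm * 1e-7
        return (np.pi / 6.0) * d_cm**3

    @property
    def edge_volumes_cm3(self) -> np.ndarray:
        d_cm = self.edges_nm * 1e-7
        return (np.pi / 6.0) * d_cm**3

    @property
    def dlog10d(self) -> np.ndarray:
        return np.diff(np.log10(self.edges_nm))

    def section_of(self, diameter_nm: float) -> int:
        """Index of the section containing ``diameter_nm``."""
        if not self.edges_nm[0] <= diameter_nm <= self.edges_nm[-1]:
            raise ValueError(
                f"diameter {diameter_nm} nm outside grid "
                f"[{self.edges_nm[0]}, {self.edges_nm[-1]}] nm"
            )
        i = int(np.searchsorted(self.edges_nm, diameter_nm, side="right") - 1)
        return min(i, self.n_sections - 1)

    def mask_below(self, diameter_nm: float) -> np.ndarray:
        """Boolean mask of sections whose centers lie below ``diameter_nm``."""
        return self.centers_nm < diameter_nm

    def mask_between(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        return (self.centers_nm >= lo_nm) & (self.centers_nm < hi_nm)
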