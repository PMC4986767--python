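"""From allele fraction to clone size: cells and epithelial area.

A somatic variant measured at allele fraction v in a diploid tissue sample
is carried by 2v of the sampled cells if heterozygous (v if homozygous),
capped at 1.  Scaling by the total cell count of the epithelium and the
fraction of its area the sample covered gives the clone's cell count, and
dividing by the areal cell density gives the patch area in mm^2.

Defaults describe the human lens epithelium: ~0.5e6 cells in total, a
peripheral cell density of ~5500 cells/mm^2.  The headline worked example:
a variant at 1% VAF, heterozygous, in a sample covering half the
epithelium, implies 2% of sampled cells, ~5000 cells, ~1 mm^2 of epithelium.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CloneAssumptions", "CloneEstimate",
           "cell_fraction", "clone_cells", "clone_area", "estimate_clone"]

HETEROZYGOUS = "heterozygous"
HOMOZYGOUS = "homozygous"


@dataclass
class CloneAssumptions:
    """Tissue geometry and zygosity assumptions behind a clone estimate."""

    zygosity: str = HETEROZYGOUS
    cells_total_epithelium: float = 0.5e6
    sampled_area_fraction: float = 1.0
    cell_density: float = 5500.0  # cells per mm^2

    def __post_init__(self) -> None:
        if self.zygosity not in (HETEROZYGOUS, HOMOZYGOUS):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")
        if self.cells_total_epithelium <= 0 or self.cell_density <= 0:
            raise ValueError("cell counts and density must be positive")
        if not (0 < self.sampled_area_fraction <= 1):
            raise ValueError("sampled_area_fraction must be in (0, 1]")


@dataclass
class CloneEstimate:
    """Derived clone size with the inputs that produced it."""

    vaf: float
    cell_fraction: float
    cells_sampled: float
    clone_cells: int
    clone_area_mm2: float
    clone_area_mm2_rounded: float
    assumptions: CloneAssumptions


def cell_fraction(vaf: float, zygosity: str = HETEROZYGOUS) -> float:
    """Fraction of sampled cells carrying the variant.

    Twice the allele fraction for a heterozygous variant in a diploid cell
    (capped at 1), the allele fraction itself if homozygous.
    """
    if not (0 <= vaf <= 1):
        raise ValueError("vaf must be in [0, 1]")
    if zygosity == HETEROZYGOUS:
        return min(1.0, 2.0 * vaf)
    if zygosity == HOMOZYGOUS:
        return vaf
    raise ValueError(f"unknown zygosity {zygosity!r}")


def clone_cells(fraction: float, assumptions: CloneAssumptions) -> int:
    """Cells in the clone: fraction x total epithelial cells x sampled area
    fraction, rounded to the nearest cell."""
    if not (0 <= fraction <= 1):
        raise ValueError("fraction must be in [0, 1]")
    return int(round(fraction * assumptions.cells_total_epithelium
                     * assumptions.sampled_area_fraction))


def clone_area(cells: float, density: float) -> float:
    """Patch area in mm^2 assuming uniform areal cell density."""
    if density <= 0:
        raise ValueError("density must be positive")
    if cells < 0:
        raise ValueError("cells must be non-negative")
    return cells / density


def _round_whole_mm2(area: float) -> float:
    """The 'approximately N mm^2' figure: nearest whole mm^2, falling back
    to one significant digit below half a mm^2 so tiny patches don't round
    to zero."""
    if area >= 0.5:
        return float(round(area))
    if area == 0:
        return 0.0
    from math import floor, log10
    exp = floor(log10(area))
    return round(area, -exp)


def estimate_clone(vaf: float, assumptions: CloneAssumptions | None = None
                   ) -> CloneEstimate:
    """End-to-end derivation from allele fraction to clone area."""
    a = assumptions or CloneAssumptions()
    frac = cell_fraction(vaf, a.zygosity)
    cells_sampled = a.cells_total_epithelium * a.sampled_area_fraction
    n_cells = clone_cells(frac, a)
    area = clone_area(n_cells, a.cell_density)
    return CloneEstimate(
        vaf=vaf, cell_fraction=frac, cells_sampled=cells_sampled,
        clone_cells=n_cells, clone_area_mm2=area,
        clone_area_mm2_rounded=_round_whole_mm2(area), assumptions=a,
    )
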