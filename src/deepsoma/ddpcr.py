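"""Droplet digital PCR quantification via the Poisson occupancy law.

A duplex ddPCR reaction partitions the template into ~15,000 droplets read
on two fluorescence channels: FAM reports the variant allele, HEX the wild
type.  Droplets are gated on fixed thresholds; the mean template occupancy
per droplet is recovered from the fraction of channel-negative droplets,
lambda = -ln(n_negative / n_total), and divided by the droplet volume to
give absolute copies/uL.  The variant allele fraction is then
VAF = CN_var / (CN_var + CN_wt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DropletSet", "DdpcrThresholds", "DdpcrQuant",
    "SaturationError", "UndefinedVAFError",
    "classify_droplets", "poisson_copies", "vaf_from_copies", "quantify",
    "read_droplet_csv", "write_droplet_csv",
]


class SaturationError(ValueError):
    """All droplets positive in a channel: occupancy cannot be estimated."""


class UndefinedVAFError(ValueError):
    """Both copy numbers are zero: the allele fraction is undefined."""


@dataclass
class DropletSet:
    """Per-droplet two-channel fluorescence readings."""

    fam: np.ndarray
    hex: np.ndarray

    def __post_init__(self) -> None:
        self.fam = np.asarray(self.fam, dtype=float)
        self.hex = np.asarray(self.hex, dtype=float)
        if self.fam.shape != self.hex.shape or self.fam.ndim != 1:
            raise ValueError("fam and hex must be 1-D arrays of equal length")
        if self.fam.size == 0:
            raise ValueError("droplet set must be non-empty")
        if (self.fam < 0).any() or (self.hex < 0).any():
            raise ValueError("fluorescence signals must be non-negative")

    @property
    def n_total(self) -> int:
        return int(self.fam.size)


@dataclass
class DdpcrThresholds:
    """Channel gates.  A droplet is called variant-only when FAM exceeds
    ``fam_min_positive`` while HEX stays below ``hex_min_positive``;
    wild-type positivity is HEX >= ``hex_min_positive``.  Droplets high in
    both channels are double-positive and carry template of both kinds."""

    fam_min_positive: float = 4000.0
    hex_min_positive: float = 3000.0

    def __post_init__(self) -> None:
        if self.fam_min_positive <= 0 or self.hex_min_positive <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class DdpcrQuant:
    """Full quantification of one reaction."""

    n_var_pos: int
    n_wt_pos: int
    n_double: int
    n_empty: int
    n_total: int
    lambda_var: float
    lambda_wt: float
    cn_var: float
    cn_wt: float
    vaf: float
    v_droplet: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify_droplets(d: DropletSet, t: DdpcrThresholds
                      ) -> tuple[int, int, int, int]:
    """Exhaustive, mutually exclusive droplet classification.

    Returns (n_var_pos, n_wt_pos, n_double, n_empty).  Variant-only
    droplets satisfy FAM > fam_min_positive and HEX < hex_min_positive;
    wild-type-only the complement; double-positives are high in both.  For
    Poisson occupancy each channel's positive count is its single-positive
    count plus the double-positives.
    """
    fam_hi = d.fam > t.fam_min_positive
    wt_hi = d.hex >= t.hex_min_positive
    n_double = int((fam_hi & wt_hi).sum())
    n_var = int((fam_hi & ~wt_hi).sum())
    n_wt = int((wt_hi & ~fam_hi).sum())
    n_empty = d.n_total - n_double - n_var - n_wt
    return n_var, n_wt, n_double, n_empty


def poisson_copies(n_channel_positive: int, n_total: int,
                   v_droplet: float) -> float:
    """Absolute concentration from a channel's positive-droplet count.

    lambda = -ln(1 - n_positive / n_total); returns lambda / v_droplet in
    copies/uL.  A fully positive channel is saturated and raises.
    """
    if not (0 <= n_channel_positive <= n_total):
        raise ValueError("need 0 <= n_channel_positive <= n_total")
    if v_droplet <= 0:
        raise ValueError("v_droplet must be positive")
    if n_channel_positive == n_total:
        raise SaturationError(
            "every droplet positive: occupancy is unbounded at this dilution")
    lam = -math.log1p(-n_channel_positive / n_total)
    return lam / v_droplet


def vaf_from_copies(cn_var: float, cn_wt: float) -> float:
    """VAF = CN_var / (CN_var + CN_wt)."""
    if cn_var < 0 or cn_wt < 0:
        raise ValueError("copy numbers must be non-negative")
    if cn_var + cn_wt == 0:
        raise UndefinedVAFError("both copy numbers zero: VAF undefined")
    return cn_var / (cn_var + cn_wt)


def quantify(d: DropletSet, t: DdpcrThresholds | None = None,
             v_droplet: float = 0.00085) -> DdpcrQuant:
    """Classify droplets and recover copy numbers and allele fraction."""
    t = t or DdpcrThresholds()
    n_var, n_wt, n_double, n_empty = classify_droplets(d, t)
    pos_var = n_var + n_double
    pos_wt = n_wt + n_double
    cn_var = poisson_copies(pos_var, d.n_total, v_droplet)
    cn_wt = poisson_copies(pos_wt, d.n_total, v_droplet)
    vaf = vaf_from_copies(cn_var, cn_wt)  # raises UndefinedVAFError if both 0
    return DdpcrQuant(
        n_var_pos=n_var, n_wt_pos=n_wt, n_double=n_double, n_empty=n_empty,
        n_total=d.n_total,
        lambda_var=cn_var * v_droplet, lambda_wt=cn_wt * v_droplet,
        cn_var=cn_var, cn_wt=cn_wt, vaf=vaf, v_droplet=v_droplet,
    )


def write_droplet_csv(d: DropletSet, path) -> None:
    pd.DataFrame({
        "droplet_id": np.arange(d.n_total),
        "fam_signal": d.fam,
        "hex_signal": d.hex,
    }).to_csv(path, index=False)


def read_droplet_csv(path) -> DropletSet:
    df = pd.read_csv(path)
    for col in ("fam_signal", "hex_signal"):
        if col not in df.columns:
            raise ValueError(f"droplet CSV missing column {col!r}")
    return DropletSet(fam=df["fam_signal"].to_numpy(),
                      hex=df["hex_signal"].to_numpy())
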