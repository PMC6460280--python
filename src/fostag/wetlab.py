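"""Subcloning primer design and enzyme-assay arithmetic.

The computational residue of downstream validation work: building PCR
primers for directional TOPO or restriction-site cloning of a predicted
CDS, and converting colorimetric protease measurements (tyrosine released
from casein, read against a standard curve) into U/ml, where one unit
releases 1 µmol tyrosine per minute per millilitre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import revcomp

# common 6-cutter recognition sites for restriction-mode primer design
ENZYME_SITES = {
    "PstI": "CTGCAG",
    "EcoRI": "GAATTC",
    "BamHI": "GGATCC",
    "HindIII": "AAGCTT",
    "XhoI": "CTCGAG",
    "NdeI": "CATATG",
}

TOPO_ADAPTOR = "CACC"  # directional TOPO fwd-primer leader
RESTRICTION_PAD = "AA"  # spacer bases ahead of the recognition site


@dataclass(frozen=True)
class PrimerDesign:
    gene_id: str
    mode: str  # directional_topo | restriction
    fwd: str
    rev: str
    adaptor: str
    fwd_adaptor_span: tuple[int, int]  # adaptor interval on the fwd primer
    rev_adaptor_span: tuple[int, int]
    internal_site_conflict: bool
    tm_fwd: float
    tm_rev: float
    tm_out_of_range: bool


def wallace_tm(seq: str) -> float:
    """Wallace 2/4 rule: 2 °C per A/T plus 4 °C per G/C."""
    return 2.0 * (seq.count("A") + seq.count("T")) + 4.0 * (seq.count("G") + seq.count("C"))


def design_primers(
    cds: str,
    gene_id: str,
    mode: str = "directional_topo",
    enzyme: str | None = None,
    gene_specific_len: int = 18,
    rev_gene_specific_len: int | None = None,
    fwd_offset: int = 0,
    tm_window: tuple[float, float] = (50.0, 72.0),
) -> PrimerDesign:
    """Design a fwd/rev primer pair for subcloning a CDS.

    ``directional_topo``: fwd = ``CACC`` + the first ``gene_specific_len``
    nt from the start codon (offset by ``fwd_offset`` if needed); rev = the
    reverse complement of the 3' gene-specific segment, no adaptor.
    ``restriction``: both primers are ``AA`` + the enzyme recognition site
    + the gene-specific segment; the CDS is scanned for internal
    occurrences of the site and the conflict flag set when found, since an
    internal site would be cut along with the primer-borne ones.
    """
    if mode not in ("directional_topo", "restriction"):
        raise ValueError(f"unknown primer design mode {mode!r}")
    rev_len = rev_gene_specific_len or gene_specific_len
    if fwd_offset + gene_specific_len > len(cds) or rev_len > len(cds):
        raise ValueError("gene-specific segment extends beyond the CDS")
    fwd_segment = cds[fwd_offset : fwd_offset + gene_specific_len]
    rev_segment = revcomp(cds[-rev_len:])
    if mode == "directional_topo":
        adaptor = TOPO_ADAPTOR
        fwd = adaptor + fwd_segment
        rev = rev_segment
        fwd_span, rev_span = (0, len(adaptor)), (0, 0)
        conflict = False
    else:
        if enzyme not in ENZYME_SITES:
            raise ValueError(f"unknown restriction enzyme {enzyme!r}")
        site = ENZYME_SITES[enzyme]
        adaptor = RESTRICTION_PAD + site
        fwd = adaptor + fwd_segment
        rev = adaptor + rev_segment
        fwd_span = rev_span = (0, len(adaptor))
        conflict = site in cds or site in revcomp(cds)
    tm_f, tm_r = wallace_tm(fwd_segment), wallace_tm(rev_segment if mode != "directional_topo" else rev)
    lo, hi = tm_window
    return PrimerDesign(
        gene_id=gene_id,
        mode=mode,
        fwd=fwd,
        rev=rev,
        adaptor=adaptor,
        fwd_adaptor_span=fwd_span,
        rev_adaptor_span=rev_span,
        internal_site_conflict=conflict,
        tm_fwd=tm_f,
        tm_rev=tm_r,
        tm_out_of_range=not (lo <= tm_f <= hi and lo <= tm_r <= hi),
    )


def protease_units(released_umol: float, minutes: float, ml: float) -> float:
    """Protease activity in U/ml: µmol tyrosine released / (min × ml)."""
    if minutes <= 0 or ml <= 0:
        raise ValueError("incubation time and extract volume must be positive")
    if released_umol < 0:
        raise ValueError("released tyrosine cannot be negative")
    return released_umol / (minutes * ml)


@dataclass(frozen=True)
class ActivityResult:
    sample_id: str
    released_umol: float
    minutes: float
    ml: float

    @property
    def units_per_ml(self) -> float:
        return protease_units(self.released_umol, self.minutes, self.ml)


class StandardCurveError(ValueError):
    pass


@dataclass
class StandardCurve:
    """Least-squares linear tyrosine standard curve (µmol vs absorbance).

    The calibrated concentration range (0.110–1.5 µmol in the assay this
    mirrors) is recorded; inversions outside the calibrated absorbance
    range are returned with an extrapolation flag rather than refused.
    """

    concentrations_umol: tuple[float, ...]
    absorbances: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.concentrations_umol) != len(self.absorbances):
            raise StandardCurveError("concentration/absorbance lengths differ")
        if len(self.concentrations_umol) < 3:
            raise StandardCurveError("standard curve needs at least 3 points")
        fit = stats.linregress(self.concentrations_umol, self.absorbances)
        if abs(fit.slope) < 1e-12:
            raise StandardCurveError("degenerate standard curve: zero slope")
        self.slope = float(fit.slope)
        self.intercept = float(fit.intercept)
        self.r_value = float(fit.rvalue)

    @property
    def absorbance_range(self) -> tuple[float, float]:
        pred = self.slope * np.asarray(self.concentrations_umol) + self.intercept
        return float(pred.min()), float(pred.max())

    def tyrosine_from_absorbance(self, absorbance: float) -> tuple[float, bool]:
        """Invert the fitted line; flags absorbances outside calibration.

        Returns (µmol tyrosine, extrapolated).
        """
        lo, hi = self.absorbance_range
        extrapolated = not (lo <= absorbance <= hi)
        return (absorbance - self.intercept) / self.slope, extrapolated


def tyrosine_from_absorbance(curve: StandardCurve, absorbance: float) -> tuple[float, bool]:
    """Module-level convenience wrapper around the curve's inversion."""
    return curve.tyrosine_from_absorbance(absorbance)
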