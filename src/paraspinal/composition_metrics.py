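"""Cross-sectional-area and fat-signal-fraction measures for one ROI.

Four measures summarize the composition of a region of interest:

* tCSA — total cross-sectional area, the full pixel count of the ROI
  converted to mm^2 by the pixel area;
* FSF — fat signal fraction, fat pixels over all ROI pixels;
* mCSA — muscle cross-sectional area, ``tCSA - tCSA * FSF``;
* fCSA — fat cross-sectional area, ``tCSA * FSF``.

mCSA + fCSA = tCSA is an algebraic identity, and FSF never depends on the
pixel spacing. Each pixel is wholly fat or wholly muscle — no
partial-volume weighting — as the hard intensity threshold implies. Both
the raw pixel count and the mm^2 value of tCSA are stored so the area
scale is always unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import EmptyRoiError
from .tissue_threshold import TissueLabels


@dataclass(frozen=True)
class CompositionMeasures:
    """The four composition measures for one labelled ROI."""

    tcsa_mm2: float
    tcsa_px: int
    fsf: float
    mcsa_mm2: float
    fcsa_mm2: float
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.fsf <= 1.0:
            raise ValueError(f"fsf must be in [0, 1], got {self.fsf}")

    def as_record(self) -> dict:
        rec = dict(self.labels)
        rec.update(
            tcsa_mm2=self.tcsa_mm2,
            tcsa_px=self.tcsa_px,
            fsf=self.fsf,
            mcsa_mm2=self.mcsa_mm2,
            fcsa_mm2=self.fcsa_mm2,
        )
        return rec


def compute_composition(
    labels: TissueLabels,
    pixel_spacing: tuple[float, float],
    roi_labels: dict | None = None,
) -> CompositionMeasures:
    """Compute tCSA, FSF, mCSA and fCSA from tissue labels and pixel geometry.

    ``fCSA = tCSA * FSF`` and ``mCSA = tCSA - fCSA`` are evaluated exactly
    in that order so the mCSA + fCSA = tCSA identity holds to the last
    floating-point bit.
    """
    n_fat, n_muscle = labels.n_fat, labels.n_muscle
    n_total = n_fat + n_muscle
    if n_total <= 0:
        raise EmptyRoiError("no labelled pixels: cannot compute composition")
    pixel_area = float(pixel_spacing[0]) * float(pixel_spacing[1])
    tcsa = n_total * pixel_area
    fsf = n_fat / n_total
    fcsa = tcsa * fsf
    mcsa = tcsa - fcsa
    return CompositionMeasures(
        tcsa_mm2=tcsa,
        tcsa_px=n_total,
        fsf=fsf,
        mcsa_mm2=mcsa,
        fcsa_mm2=fcsa,
        labels=dict(roi_labels or {}),
    )
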