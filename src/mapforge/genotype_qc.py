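"""Locus and line filters applied before linkage analysis.

Markers are filtered first: a marker is dropped if its missing fraction
exceeds ``max_missing`` (strictly) or if a 1-df chi-square test of its A:B
homozygote counts against 1:1 is significant at ``alpha``. Heterozygous and
missing calls are excluded from the distortion counts; no continuity
correction is applied. Lines are then filtered on their missing fraction
over the retained markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import A, B, MISSING, GenotypeMatrix, MapforgeError


@dataclass
class QcReport:
    n_input_markers: int = 0
    n_markers_removed_missing: int = 0
    n_markers_removed_distortion: int = 0
    n_markers_removed_uninformative: int = 0
    n_input_lines: int = 0
    n_lines_removed_missing: int = 0
    per_marker: pd.DataFrame = field(default_factory=pd.DataFrame)
    metadata: dict = field(default_factory=dict)


def segregation_chi2(n_a: np.ndarray, n_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chi-square statistic and p-value of A:B counts against 1:1 (1 df)."""
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    total = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(total > 0, (n_a - n_b) ** 2 / np.where(total > 0, total, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    return chi2, p


def filter_markers(
    g: GenotypeMatrix, max_missing: float = 0.10, alpha: float = 0.01
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers with missing fraction > ``max_missing`` or segregation
    distortion at p < ``alpha``; marker order is preserved. Markers with no
    homozygous calls at all are dropped as uninformative."""
    if g.n_markers == 0 or g.n_lines == 0:
        raise MapforgeError("cannot QC an empty genotype matrix")
    miss = g.marker_missing_fraction()
    n_a = (g.calls == A).sum(axis=1)
    n_b = (g.calls == B).sum(axis=1)
    chi2, p = segregation_chi2(n_a, n_b)
    uninformative = (n_a + n_b) == 0
    too_missing = miss > max_missing
    distorted = ~uninformative & (p < alpha)
    keep = ~(too_missing | distorted | uninformative)

    report = QcReport(
        n_input_markers=g.n_markers,
        n_markers_removed_missing=int(too_missing.sum()),
        n_markers_removed_distortion=int((distorted & ~too_missing).sum()),
        n_markers_removed_uninformative=int((uninformative & ~too_missing).sum()),
        n_input_lines=g.n_lines,
        per_marker=pd.DataFrame(
            {
                "marker_id": g.marker_ids,
                "missing_fraction": miss,
                "chi2": chi2,
                "p": p,
                "removed": ~keep,
                "flag": np.where(
                    uninformative, "uninformative",
                    np.where(too_missing, "missing", np.where(distorted, "distorted", "")),
                ),
            }
        ),
        metadata={"max_missing": max_missing, "alpha": alpha,
                  "test": "chi2 1df A:B vs 1:1, H/missing excluded, no continuity correction"},
    )
    return g.subset(marker_mask=keep), report


def filter_lines(g: GenotypeMatrix, max_missing: float = 0.10) -> tuple[GenotypeMatrix, QcReport]:
    """Drop lines whose missing fraction over the (already filtered) markers
    strictly exceeds ``max_missing``."""
    if g.n_markers == 0 or g.n_lines == 0:
        raise MapforgeError("cannot QC an empty genotype matrix")
    miss = g.line_missing_fraction()
    keep = miss <= max_missing
    if not keep.any():
        raise MapforgeError("all lines exceed the missing-data threshold: empty population")
    report = QcReport(
        n_input_markers=g.n_markers,
        n_input_lines=g.n_lines,
        n_lines_removed_missing=int((~keep).sum()),
        metadata={"max_missing": max_missing},
    )
    return g.subset(line_mask=keep), report


def run_qc(
    g: GenotypeMatrix, max_missing: float = 0.10, alpha: float = 0.01
) -> tuple[GenotypeMatrix, QcReport]:
    """Markers first, then lines; the combined report records both stages."""
    g1, rep_m = filter_markers(g, max_missing=max_missing, alpha=alpha)
    g2, rep_l = filter_lines(g1, max_missing=max_missing)
    rep_m.n_lines_removed_missing = rep_l.n_lines_removed_missing
    rep_m.n_input_lines = g.n_lines
    rep_m.metadata["order"] = "markers_then_lines"
    return g2, rep_m
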