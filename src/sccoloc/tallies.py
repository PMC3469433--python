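"""Descriptive scoring of a stretch set: GFP-vs-Zip3 category tallies and
centromere-association tallies.

GFP elements are split into three size classes — focus (< 0.35 µm),
short stretch ([0.35, 0.5) µm) and long stretch (>= 0.5 µm) — the
half-open bounds making the classes a partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import Category, StretchSet, classify_focus

__all__ = [
    "TallyReport",
    "CentromereReport",
    "size_class",
    "tally_gfp_vs_zip3",
    "tally_centromeres",
]

DEFAULT_SIZE_CLASS_BOUNDS = (0.35, 0.5)
SIZE_CLASSES = ("focus", "short_stretch", "long_stretch")


def size_class(length: float, bounds: tuple[float, float] = DEFAULT_SIZE_CLASS_BOUNDS) -> str:
    lo, hi = bounds
    if length < lo:
        return "focus"
    if length < hi:
        return "short_stretch"
    return "long_stretch"


@dataclass
class TallyReport:
    n_foci: int
    n_encompassed: int
    n_partial: int
    n_touching: int
    n_none: int
    by_size_class: dict = field(default_factory=dict)

    @property
    def percentages(self) -> dict:
        if self.n_foci == 0:
            return {c: 0.0 for c in ("encompassed", "partial", "touching", "none")}
        return {
            "encompassed": 100.0 * self.n_encompassed / self.n_foci,
            "partial": 100.0 * self.n_partial / self.n_foci,
            "touching": 100.0 * self.n_touching / self.n_foci,
            "none": 100.0 * self.n_none / self.n_foci,
        }

    @property
    def adjacency_fraction(self) -> float:
        """Fraction touching, overlapping or encompassed (the 'adjacent'
        headline quantity)."""
        if self.n_foci == 0:
            return 0.0
        return (self.n_encompassed + self.n_partial + self.n_touching) / self.n_foci

    def to_dict(self) -> dict:
        return {
            "n_foci": self.n_foci,
            "n_encompassed": self.n_encompassed,
            "n_partial": self.n_partial,
            "n_touching": self.n_touching,
            "n_none": self.n_none,
            "percentages": self.percentages,
            "adjacency_fraction": self.adjacency_fraction,
            "by_size_class": self.by_size_class,
        }


@dataclass
class CentromereReport:
    n_centromeres: int
    n_with_focus: int
    n_with_stretch: int
    n_without: int
    per_stretch_gfp_at_cen_fraction: dict = field(default_factory=dict)
    cen_window: float = 0.0

    def to_dict(self) -> dict:
        mean_frac = (
            sum(self.per_stretch_gfp_at_cen_fraction.values())
            / len(self.per_stretch_gfp_at_cen_fraction)
            if self.per_stretch_gfp_at_cen_fraction
            else 0.0
        )
        return {
            "n_centromeres": self.n_centromeres,
            "n_with_focus": self.n_with_focus,
            "n_with_stretch": self.n_with_stretch,
            "n_without": self.n_without,
            "cen_window_um": self.cen_window,
            "per_stretch_gfp_at_cen_fraction": self.per_stretch_gfp_at_cen_fraction,
            "mean_gfp_at_cen_fraction": mean_frac,
        }


_CAT_FIELD = {
    Category.ENCOMPASSED: "n_encompassed",
    Category.PARTIAL_OVERLAP: "n_partial",
    Category.TOUCHING: "n_touching",
    Category.NONE: "n_none",
}


def tally_gfp_vs_zip3(
    data: StretchSet,
    touch_tolerance: float = 0.0,
    size_class_bounds: tuple[float, float] = DEFAULT_SIZE_CLASS_BOUNDS,
) -> TallyReport:
    """Classify every GFP element against its stretch's Zip3 foci and
    aggregate overall and per size class."""
    counts = {f: 0 for f in _CAT_FIELD.values()}
    by_class = {
        c: {f: 0 for f in _CAT_FIELD.values()} | {"n_foci": 0} for c in SIZE_CLASSES
    }
    n = 0
    for s in data:
        for f in s.gfp:
            cat = classify_focus(f, s.zip3, touch_tolerance)
            counts[_CAT_FIELD[cat]] += 1
            cls = size_class(f.length, size_class_bounds)
            by_class[cls][_CAT_FIELD[cat]] += 1
            by_class[cls]["n_foci"] += 1
            n += 1
    return TallyReport(n_foci=n, by_size_class=by_class, **counts)


def _interval_gap(a_start, a_end, b_start, b_end) -> float:
    return max(b_start - a_end, a_start - b_end, 0.0)


def tally_centromeres(
    data: StretchSet,
    cen_window: float = 0.35,
    size_class_bounds: tuple[float, float] = DEFAULT_SIZE_CLASS_BOUNDS,
    stretch_over_focus: bool = True,
) -> CentromereReport:
    """Assign each centromere to exactly one category — colocalized with a
    GFP *focus*, with a GFP *stretch* (short or long), or with nothing —
    by the GFP elements lying within ``cen_window`` µm.

    When a centromere is near both a focus-class and a stretch-class
    element the precedence is controlled by ``stretch_over_focus``
    (default: stretch wins). Also reports, per SC stretch, the fraction
    of its GFP elements lying within ``cen_window`` of its centromere.
    """
    if not any(s.cen is not None for s in data):
        raise ValueError("no CEN annotations in stretch set")
    n_cen = n_focus = n_stretch = n_without = 0
    fractions: dict[str, float] = {}
    for s in data:
        if s.cen is None:
            continue
        n_cen += 1
        near = [
            f
            for f in s.gfp
            if _interval_gap(f.start, f.end, s.cen.start, s.cen.end) <= cen_window
        ]
        if s.gfp:
            fractions[s.id] = len(near) / len(s.gfp)
        if not near:
            n_without += 1
            continue
        classes = {size_class(f.length, size_class_bounds) for f in near}
        has_stretch = bool(classes & {"short_stretch", "long_stretch"})
        has_focus = "focus" in classes
        if has_stretch and (stretch_over_focus or not has_focus):
            n_stretch += 1
        else:
            n_focus += 1
    return CentromereReport(
        n_centromeres=n_cen,
        n_with_focus=n_focus,
        n_with_stretch=n_stretch,
        n_without=n_without,
        per_stretch_gfp_at_cen_fraction=fractions,
        cen_window=cen_window,
    )
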