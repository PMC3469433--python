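"""Core 1D geometry for synaptonemal-complex (SC) colocalization analysis.

An SC stretch is modelled as a closed segment ``[0, L]`` in micrometres.
Zip3 marker foci and Zip1-GFP incorporation foci are closed sub-intervals;
a centromere marker may be a zero-length point. The colocalization
criteria are expressed as *domains*: for a GFP focus of length ``g``, the
set of centre positions on the stretch that would score a hit.

Two criteria are supported:

* **adjacency** — the GFP focus touches, partially overlaps, or is
  completely encompassed by a Zip3 focus. A focus of length ``g`` hits
  exactly when its centre lies in ``[zip3.start - g/2, zip3.end + g/2]``.
* **encompassment** — the GFP focus lies entirely inside a Zip3 focus.
  The centre must lie in ``[zip3.start + g/2, zip3.end - g/2]``, which is
  empty when ``g`` exceeds the Zip3 focus length.

Boundary coincidences (measure zero under continuous placement) are
resolved inclusively throughout.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Label",
    "Category",
    "Mode",
    "BoundaryPolicy",
    "FocusInterval",
    "Stretch",
    "StretchSet",
    "SizeDistribution",
    "DomainSet",
    "InvalidSizeError",
    "legal_center_range",
    "adjacency_domain",
    "encompassment_domain",
    "domain_union",
    "stretch_domain",
    "classify_focus",
]


class Label(str, enum.Enum):
    ZIP3 = "ZIP3"
    GFP = "GFP"
    CEN = "CEN"


class Category(str, enum.Enum):
    """Classification of one GFP focus relative to a set of Zip3 foci.

    Ordered from strongest to weakest; when several Zip3 foci qualify the
    strongest category wins.
    """

    ENCOMPASSED = "ENCOMPASSED"
    PARTIAL_OVERLAP = "PARTIAL_OVERLAP"
    TOUCHING = "TOUCHING"
    NONE = "NONE"


class Mode(str, enum.Enum):
    ADJACENCY = "adjacency"
    ENCOMPASSMENT = "encompassment"


class BoundaryPolicy(str, enum.Enum):
    """Edge rule for legal GFP centre positions on a stretch of length L.

    CONTAINED restricts centres to ``[g/2, L - g/2]`` so a placed focus
    lies wholly on the stretch; UNCONSTRAINED allows centres anywhere in
    ``[0, L]`` (foci may overhang the ends).
    """

    CONTAINED = "contained"
    UNCONSTRAINED = "unconstrained"


class InvalidSizeError(ValueError):
    """Raised when a focus length is non-positive."""


@dataclass(frozen=True)
class FocusInterval:
    """A 1D focus interval on a stretch, in µm; CEN markers may be points."""

    start: float
    end: float
    label: Label = Label.GFP

    def __post_init__(self) -> None:
        if not (0.0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}]: need 0 <= start <= end"
            )

    @property
    def length(self) -> float:
        return self.end - self.start

    @property
    def center(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class Stretch:
    """One linear SC segment with the labelled intervals it carries.

    ``n_gfp_constraint`` is the number of GFP foci a constrained null
    placement must put on this stretch; it defaults to the observed number.
    """

    id: str
    length: float
    zip3: list[FocusInterval] = field(default_factory=list)
    gfp: list[FocusInterval] = field(default_factory=list)
    cen: FocusInterval | None = None
    n_gfp_constraint: int | None = None

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"stretch {self.id!r}: length must be > 0")
        for iv in [*self.zip3, *self.gfp, *([self.cen] if self.cen else [])]:
            if iv.end > self.length + 1e-12:
                raise ValueError(
                    f"stretch {self.id!r}: interval [{iv.start}, {iv.end}] "
                    f"exceeds stretch length {self.length}"
                )
        if self.n_gfp_constraint is None:
            self.n_gfp_constraint = len(self.gfp)
        if self.n_gfp_constraint < 0:
            raise ValueError(f"stretch {self.id!r}: n_gfp_constraint must be >= 0")

    def zip3_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Zip3 (starts, ends) sorted by start, as float arrays."""
        if not self.zip3:
            return np.empty(0), np.empty(0)
        order = sorted(range(len(self.zip3)), key=lambda i: self.zip3[i].start)
        starts = np.array([self.zip3[i].start for i in order], dtype=float)
        ends = np.array([self.zip3[i].end for i in order], dtype=float)
        return starts, ends


@dataclass
class StretchSet:
    stretches: list[Stretch]
    name: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.stretches]
        if len(set(ids)) != len(ids):
            raise ValueError("stretch ids must be unique")

    @property
    def n_gfp_total(self) -> int:
        return sum(len(s.gfp) for s in self.stretches)

    @property
    def n_gfp_constraint_total(self) -> int:
        return sum(s.n_gfp_constraint for s in self.stretches)

    def __iter__(self):
        return iter(self.stretches)


@dataclass(frozen=True)
class SizeDistribution:
    """Empirical bag of GFP focus lengths (µm) resampled by the null."""

    sizes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.sizes) == 0:
            raise ValueError("SizeDistribution must be non-empty")
        if any(s <= 0 for s in self.sizes):
            raise ValueError("all focus sizes must be > 0")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=float)

    def sample(self, rng: np.random.Generator, n: int | tuple = 1) -> np.ndarray:
        return rng.choice(self.as_array(), size=n, replace=True)

    @classmethod
    def from_stretch_set(cls, data: StretchSet) -> "SizeDistribution":
        sizes = tuple(f.length for s in data for f in s.gfp)
        return cls(sizes)


@dataclass(frozen=True)
class DomainSet:
    """Merged set of legal hit-scoring centre positions on one stretch.

    ``total_measure`` is the Lebesgue measure of the union;
    ``allowed_measure`` is the measure of all legal centre positions.
    """

    stretch_id: str
    intervals: tuple[tuple[float, float], ...]
    total_measure: float
    allowed_measure: float

    def boundaries(self) -> np.ndarray:
        """Flat sorted boundary array; a point is inside iff its
        ``searchsorted`` index is odd."""
        return np.asarray([b for iv in self.intervals for b in iv], dtype=float)


def legal_center_range(
    g: float, stretch_length: float, boundary_policy: BoundaryPolicy | str
) -> tuple[float, float]:
    """Legal GFP-centre range ``(lo, hi)`` implied by the boundary policy.

    Under CONTAINED and ``g >= L`` the range is empty (``lo >= hi``); a
    warning is emitted and callers decide whether that is an error.
    """
    if g <= 0:
        raise InvalidSizeError(f"focus size must be > 0, got {g}")
    policy = BoundaryPolicy(boundary_policy)
    if policy is BoundaryPolicy.CONTAINED:
        lo, hi = 0.5 * g, stretch_length - 0.5 * g
        if lo >= hi:
            warnings.warn(
                f"focus of length {g} µm cannot be contained on a "
                f"{stretch_length} µm stretch; legal centre range is empty",
                stacklevel=2,
            )
        return lo, hi
    return 0.0, stretch_length


def _clip(interval: tuple[float, float], lo: float, hi: float):
    a, b = max(interval[0], lo), min(interval[1], hi)
    if a > b:
        return None
    return (a, b)


def adjacency_domain(
    zip3: FocusInterval,
    g: float,
    stretch_length: float,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
) -> tuple[float, float] | None:
    """Centre positions at which a focus of length ``g`` touches, overlaps
    or is encompassed by ``zip3``: the Zip3 interval widened by ``g/2`` on
    each side, clipped to the legal centre range."""
    lo, hi = legal_center_range(g, stretch_length, boundary_policy)
    return _clip((zip3.start - 0.5 * g, zip3.end + 0.5 * g), lo, hi)


def encompassment_domain(
    zip3: FocusInterval,
    g: float,
    stretch_length: float,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
) -> tuple[float, float] | None:
    """Centre positions at which a focus of length ``g`` lies entirely
    inside ``zip3``: the Zip3 interval shrunk by ``g/2`` from each
    boundary; ``None`` (empty) when ``g`` exceeds the Zip3 length."""
    lo, hi = legal_center_range(g, stretch_length, boundary_policy)
    a, b = zip3.start + 0.5 * g, zip3.end - 0.5 * g
    if a > b:
        return None
    return _clip((a, b), lo, hi)


def domain_union(
    contributions: list[tuple[float, float] | None],
    allowed_range: tuple[float, float],
) -> tuple[tuple[tuple[float, float], ...], float]:
    """Merge per-Zip3 domain contributions into a disjoint sorted union
    clipped to ``allowed_range``; returns ``(intervals, total_measure)``.

    A centre inside two overlapping contributions is counted once.
    Zero-length contributions are dropped (measure zero).
    """
    lo, hi = allowed_range
    ivs = []
    for c in contributions:
        if c is None:
            continue
        clipped = _clip(c, lo, hi)
        if clipped is not None and clipped[1] > clipped[0]:
            ivs.append(clipped)
    if not ivs:
        return (), 0.0
    ivs.sort()
    merged = [list(ivs[0])]
    for a, b in ivs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = tuple((a, b) for a, b in merged)
    return out, float(sum(b - a for a, b in out))


def _merged_bounds(
    z_starts: np.ndarray,
    z_ends: np.ndarray,
    g: float,
    mode: Mode,
    lo: float,
    hi: float,
) -> tuple[np.ndarray, float]:
    """Vectorized domain union for the hot path.

    Returns the flat boundary array (inside iff searchsorted index is odd)
    and the union measure. ``z_starts``/``z_ends`` must be sorted by start.
    """
    if z_starts.size == 0 or lo >= hi:
        return np.empty(0), 0.0
    if mode is Mode.ADJACENCY:
        a = z_starts - 0.5 * g
        b = z_ends + 0.5 * g
    else:
        a = z_starts + 0.5 * g
        b = z_ends - 0.5 * g
        keep = b > a
        a, b = a[keep], b[keep]
    if a.size == 0:
        return np.empty(0), 0.0
    np.clip(a, lo, hi, out=a)
    np.clip(b, lo, hi, out=b)
    keep = b > a
    a, b = a[keep], b[keep]
    if a.size == 0:
        return np.empty(0), 0.0
    order = np.argsort(a, kind="stable")
    a, b = a[order], b[order]
    cummax = np.maximum.accumulate(b)
    new = np.empty(a.size, dtype=bool)
    new[0] = True
    new[1:] = a[1:] > cummax[:-1]
    starts = a[new]
    grp = np.cumsum(new) - 1
    ends = np.zeros(starts.size)
    np.maximum.at(ends, grp, b)
    bounds = np.empty(2 * starts.size)
    bounds[0::2] = starts
    bounds[1::2] = ends
    return bounds, float(np.sum(ends - starts))


def stretch_domain(
    stretch: Stretch,
    g: float,
    mode: Mode | str,
    boundary_policy: BoundaryPolicy | str = BoundaryPolicy.CONTAINED,
) -> DomainSet:
    """The full hit-scoring domain of one stretch for focus size ``g``."""
    mode = Mode(mode)
    lo, hi = legal_center_range(g, stretch.length, boundary_policy)
    allowed = max(0.0, hi - lo)
    maker = adjacency_domain if mode is Mode.ADJACENCY else encompassment_domain
    contributions = [
        maker(z, g, stretch.length, boundary_policy) for z in stretch.zip3
    ]
    intervals, measure = domain_union(contributions, (min(lo, hi), hi))
    return DomainSet(
        stretch_id=stretch.id,
        intervals=intervals,
        total_measure=measure,
        allowed_measure=allowed,
    )


def classify_focus(
    gfp: FocusInterval,
    zip3_list: list[FocusInterval],
    touch_tolerance: float = 0.0,
) -> Category:
    """Classify one GFP focus against all Zip3 foci on its stretch.

    ENCOMPASSED if the GFP interval is a subset of some Zip3 interval;
    else PARTIAL_OVERLAP if interiors intersect; else TOUCHING if the gap
    to the nearest Zip3 focus is at most ``touch_tolerance``; else NONE.
    """
    best = Category.NONE
    for z in zip3_list:
        if z.start <= gfp.start and gfp.end <= z.end:
            return Category.ENCOMPASSED
        if gfp.start < z.end and z.start < gfp.end:
            cat = Category.PARTIAL_OVERLAP
        else:
            gap = max(z.start - gfp.end, gfp.start - z.end)
            cat = Category.TOUCHING if gap <= touch_tolerance else Category.NONE
        if _rank(cat) < _rank(best):
            best = cat
    return best


_ORDER = {
    Category.ENCOMPASSED: 0,
    Category.PARTIAL_OVERLAP: 1,
    Category.TOUCHING: 2,
    Category.NONE: 3,
}


def _rank(cat: Category) -> int:
    return _ORDER[cat]
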