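"""The 41-point external-ear landmark template.

The pinna is described by seven named curves — outer helix, inner helix,
lobe, tragus, antitragus, crus helicis and concha — plus one free anatomical
point (the intertragic incisure). Interior points of each curve are
semilandmarks that are allowed to slide tangentially during superimposition;
the first and last point of every curve, and all free points, are fixed
anatomical anchors. The antihelix carries no landmarks: antihelix points are
not reproducible between annotators and are excluded from the catalogue.

Coordinates follow the image convention: x grows rightward, y grows
downward, origin at the top-left of the photograph. The template describes a
right ear; left ears are handled by explicit reflection (see
:mod:`earmorph.procrustes`).
"""

from __future__ import annotations

from dataclasses import dataclass, field


N_POINTS = 41

# curve name -> number of points (ordered runs of template indices)
_SEGMENT_SIZES = {
    "outer_helix": 12,
    "inner_helix": 8,
    "concha": 6,
    "lobe": 5,
    "tragus": 3,
    "antitragus": 3,
    "crus_helicis": 3,
}
_FREE_POINTS = ("incisura_intertragica",)


@dataclass(frozen=True)
class EarTemplate:
    """Fixed catalogue of the 41 ear landmarks and their curve structure.

    Attributes
    ----------
    point_names
        Ordered landmark identifiers, length 41.
    segments
        Mapping curve name -> ordered tuple of point indices along the curve.
    semilandmark_mask
        Per-point flag; ``True`` marks a point that slides along its curve,
        ``False`` a fixed anatomical anchor. The first and last point of each
        curve and every free point are anchors.
    """

    point_names: tuple[str, ...]
    segments: dict[str, tuple[int, ...]]
    semilandmark_mask: tuple[bool, ...] = field(repr=False)

    @property
    def n_points(self) -> int:
        return len(self.point_names)

    def curve_of(self, index: int) -> str | None:
        """Name of the curve containing *index*, or None for a free point."""
        for name, run in self.segments.items():
            if index in run:
                return name
        return None

    def neighbors(self, index: int) -> tuple[int, int]:
        """Curve predecessor and successor of a semilandmark index."""
        if not self.semilandmark_mask[index]:
            raise ValueError(f"point {index} is a fixed anchor, not a semilandmark")
        for run in self.segments.values():
            if index in run:
                pos = run.index(index)
                return run[pos - 1], run[pos + 1]
        raise ValueError(f"point {index} belongs to no curve")  # pragma: no cover

    def semilandmark_indices(self) -> tuple[int, ...]:
        return tuple(i for i, m in enumerate(self.semilandmark_mask) if m)


def default_template() -> EarTemplate:
    """Build the fixed 41-point ear template.

    Deterministic and pure: repeated calls return identical structures.
    """
    names: list[str] = []
    segments: dict[str, tuple[int, ...]] = {}
    for seg, size in _SEGMENT_SIZES.items():
        start = len(names)
        names.extend(f"{seg}_{i + 1:02d}" for i in range(size))
        segments[seg] = tuple(range(start, start + size))
    names.extend(_FREE_POINTS)
    assert len(names) == N_POINTS

    mask = [False] * N_POINTS
    for run in segments.values():
        for idx in run[1:-1]:  # interior points slide; endpoints anchor
            mask[idx] = True
    return EarTemplate(
        point_names=tuple(names),
        segments=segments,
        semilandmark_mask=tuple(mask),
    )
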