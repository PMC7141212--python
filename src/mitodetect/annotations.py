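"""Ground-truth annotation container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CentroidAnnotation"]


@dataclass(frozen=True)
class CentroidAnnotation:
    """A ground-truth mitosis position.

    ``x``/``y`` are the centroid pixel coordinates (column, row). When the
    annotation came from a region-pixel list, ``region_pixels`` holds the
    pixels and the centroid is their arithmetic mean rounded to the
    nearest integer.
    """

    image_id: str
    x: float
    y: float
    class_label: str | None = None
    region_pixels: tuple[tuple[int, int], ...] | None = None

    def shifted(self, dx: float, dy: float) -> "CentroidAnnotation":
        """The same annotation with its centroid translated by (dx, dy).

        Region pixels, if any, are dropped: they are only meaningful in
        the original image frame.
        """
        return CentroidAnnotation(
            image_id=self.image_id,
            x=self.x + dx,
            y=self.y + dy,
            class_label=self.class_label,
        )
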