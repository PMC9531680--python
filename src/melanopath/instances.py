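"""Bounding-box instance annotations.

Rectangles are half-open pixel rectangles [x0, x1) x [y0, y1), 0-based,
origin at the image's top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class Box:
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    def iou(self, other: "Box") -> float:
        ix = min(self.x1, other.x1) - max(self.x0, other.x0)
        iy = min(self.y1, other.y1) - max(self.y0, other.y0)
        if ix <= 0 or iy <= 0:
            return 0.0
        inter = ix * iy
        return inter / (self.area + other.area - inter)


@dataclass
class InstanceSet:
    """Labeled boxes with optional detection scores."""

    boxes: list[Box] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    scores: list[float] | None = None

    def __post_init__(self):
        if len(self.labels) != len(self.boxes):
            raise ValueError("labels and boxes length mismatch")
        if self.scores is not None and len(self.scores) != len(self.boxes):
            raise ValueError("scores and boxes length mismatch")

    def __len__(self) -> int:
        return len(self.boxes)

    def to_json(self, path: str | Path) -> None:
        records = []
        for i, b in enumerate(self.boxes):
            rec = {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1,
                   "label": self.labels[i]}
            if self.scores is not None:
                rec["score"] = self.scores[i]
            records.append(rec)
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "InstanceSet":
        records = json.loads(Path(path).read_text())
        boxes = [Box(r["x0"], r["y0"], r["x1"], r["y1"]) for r in records]
        labels = [r["label"] for r in records]
        scores = [r["score"] for r in records] if records and "score" in records[0] else None
        return cls(boxes=boxes, labels=labels, scores=scores)
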