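"""Method parameters with the published defaults for HLS–ULS registration."""

from __future__ import annotations

from dataclasses import dataclass, asdict


@dataclass
class MethodParams:
    """Tunable parameters of the woody-salient-keypoint registration pipeline.

    Defaults are the values tuned for handheld-vs-UAV plantation scans:
    0.15 m voxel preprocessing, 0.5 m feature neighborhood, ROI threshold
    tau = 0.8 on the structural significance score, keypoint ratio
    Nr = 0.8 of the ROI (ascending wood-structure-significance order),
    0.3 m non-maximum-suppression radius, 2.0 m descriptor support,
    saliency gate delta = 0.3 on |WSS(p) - WSS(q)|, and a tuple test with
    tolerance alpha = 0.9 capped at 1000 sampled triplets.
    """

    voxel_size: float = 0.15
    feature_radius: float = 0.5
    roi_tau: float = 0.8
    keypoint_ratio: float = 0.8
    nms_radius: float = 0.3
    descriptor_radius: float = 2.0
    wss_delta: float = 0.3
    tuple_alpha: float = 0.9
    max_tuples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("voxel_size", "feature_radius", "nms_radius", "descriptor_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.keypoint_ratio <= 1:
            raise ValueError("keypoint_ratio must be in (0, 1]")
        if not 0 < self.tuple_alpha < 1:
            raise ValueError("tuple_alpha must be in (0, 1)")
        if self.wss_delta <= 0:
            raise ValueError("wss_delta must be positive")
        if self.max_tuples < 1:
            raise ValueError("max_tuples must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)
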