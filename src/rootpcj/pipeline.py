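"""End-to-end pipeline: preprocess -> thin -> label -> match -> join -> traits.

This module wires the stage modules together behind one configuration object
and returns every intermediate, so a caller (or the command-line interface)
can inspect exactly what each stage did.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from . import corrosion, features, fitjoin, phenotype, preprocess, thinning
from .corrosion import Segment
from .fitjoin import JoinCurve, MatchConfig, MatchedPair
from .phenotype import Calibration, PhenotypeRecord

__all__ = ["PipelineConfig", "RepairResult", "preprocess_image",
           "repair", "measure", "evaluate"]

log = logging.getLogger("rootpcj")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline in one declarative object.

    Round-trips losslessly through YAML via ``to_yaml``/``from_yaml``;
    unknown keys in a file are rejected rather than silently ignored.
    """

    # preprocessing
    invert: bool = False
    threshold: float | None = None       # None = automatic (Otsu)
    median_window: int = 3
    gaussian_window: int = 3
    speck_min_px: int = 20
    fill_holes: bool = False
    # matching / joining
    match: MatchConfig = field(default_factory=MatchConfig)
    # physical calibration and trait extraction
    mm_per_px: float = 0.1
    collar: tuple[int, int] | None = None
    collar_radius: float = 25.0
    diagonal_weighted_length: bool = False
    skeleton_only_bridges: bool = False
    rng_seed: int = 0

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.mm_per_px)

    def to_yaml(self, path=None) -> str:
        import yaml

        payload = asdict(self)
        if payload["collar"] is not None:
            payload["collar"] = list(payload["collar"])
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        import yaml

        if hasattr(source, "read"):
            payload = yaml.safe_load(source)
        else:
            with open(source) as fh:
                payload = yaml.safe_load(fh)
        payload = payload or {}
        match_payload = payload.pop("match", {}) or {}
        known = {f.name for f in fields(cls)} - {"match"}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        match_known = {f.name for f in fields(MatchConfig)}
        match_unknown = set(match_payload) - match_known
        if match_unknown:
            raise ValueError(f"unknown match config keys: {sorted(match_unknown)}")
        if payload.get("collar") is not None:
            payload["collar"] = tuple(payload["collar"])
        return cls(match=MatchConfig(**match_payload), **payload)


@dataclass
class RepairResult:
    """Everything a repair run produced, stage by stage."""

    mask: np.ndarray
    skeleton: np.ndarray
    labels: np.ndarray
    segments: list[Segment]
    matches: list[MatchedPair]
    joins: list[JoinCurve]
    repaired_mask: np.ndarray
    repaired_skeleton: np.ndarray
    overlay: np.ndarray
    stats: dict


def preprocess_image(image: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Raw raster to clean binary mask (grayscale, denoise, threshold, despeckle)."""
    gray = preprocess.to_grayscale(image)
    gray = preprocess.denoise(gray, "median", cfg.median_window)
    gray = preprocess.denoise(gray, "gaussian", cfg.gaussian_window)
    mask = preprocess.binarize(gray, cfg.threshold, invert=cfg.invert)
    if cfg.fill_holes:
        bg = np.argwhere(mask == 0)
        if len(bg):
            mask = preprocess.flood_background(mask, tuple(bg[0]), fill_holes=True)
    return preprocess.remove_specks(mask, cfg.speck_min_px)


def _anchored_ends(seg: Segment, junctions: np.ndarray) -> int:
    """Number of arc ends abutting a junction pixel (0 = isolated/free arc,
    2 = bridge wedged between junctions)."""
    rows, cols = junctions.shape
    count = 0
    for r, c in set(seg.ends):
        if any(0 <= r + dr < rows and 0 <= c + dc < cols
               and junctions[r + dr, c + dc]
               for dr in (-1, 0, 1) for dc in (-1, 0, 1)):
            count += 1
    return count


def repair(mask: np.ndarray, cfg: PipelineConfig | None = None) -> RepairResult:
    """Run the full repair on a binary mask.

    Stages: thinning; then, iterated to a fixed point, feature-point
    extraction, progressive corrosion into labeled arcs, and erasure of tiny
    dangling arcs (isolated specks and the short fork prongs thinning leaves
    at blunt stump ends — erasing a prong re-exposes the stump tip as a
    matchable endpoint); finally least-squares matching of arc tips, Hermite
    bridging, and reconstruction of the repaired mask and skeleton.  A tiny
    arc wedged between two junctions still carries connectivity and is never
    erased; it is merely excluded from matching.
    """
    cfg = cfg or PipelineConfig()
    mask = preprocess.as_mask(mask)
    skel = thinning.thin(mask)

    n_pruned = 0
    for cleanup_round in (0, 1):
        fps = features.extract_feature_points(skel)
        labels = corrosion.corrode(skel, corrosion.init_state(skel, fps))
        segments = corrosion.segments_from_labels(labels)
        if cleanup_round:  # erase once, then recompute on the cleaned skeleton
            break
        junctions = corrosion.junction_mask(skel)
        removable = [s for s in segments
                     if s.length_px <= cfg.match.tiny_px
                     and _anchored_ends(s, junctions) <= 1]
        for s in removable:
            for r, c in s.path:
                skel[r, c] = 0
        n_pruned = len(removable)
        if not removable:
            break

    endpoint_set = set(fps.endpoints)
    kept = fitjoin.prune_tiny(segments, cfg.match)
    feats = {s.id: fitjoin.segment_features(s, cfg.match)
             for s in kept if s.length_px >= 2}
    matches = fitjoin.match_segments(kept, feats, cfg.match, endpoint_set)
    by_id = {s.id: s for s in segments}
    joins = [fitjoin.join_pair(by_id[m.seg_a], m.end_a,
                               by_id[m.seg_b], m.end_b, cfg.match)
             for m in matches]

    repaired_mask, overlay = fitjoin.repair_image(
        mask, skel, joins, labels=labels,
        skeleton_only=cfg.skeleton_only_bridges)

    repaired_skel = skel.copy()
    for j in joins:
        for r, c in j.path:
            if 0 <= r < repaired_skel.shape[0] and 0 <= c < repaired_skel.shape[1]:
                repaired_skel[r, c] = 1

    stats = {
        "mask_px": int(mask.sum()),
        "skeleton_px": int(skel.sum()),
        "endpoints": len(fps.endpoints),
        "bifurcations": len(fps.bifurcations),
        "segments": len(segments),
        "segments_pruned": n_pruned,
        "matches": len(matches),
        "joins": len(joins),
        "components_before": _n_components(mask),
        "components_after": _n_components(repaired_mask),
    }
    for key, val in stats.items():
        log.info("%s: %s", key, val)
    return RepairResult(mask=mask, skeleton=skel, labels=labels,
                        segments=segments, matches=matches, joins=joins,
                        repaired_mask=repaired_mask,
                        repaired_skeleton=repaired_skel, overlay=overlay,
                        stats=stats)


def _n_components(mask: np.ndarray) -> int:
    from scipy import ndimage

    _, n = ndimage.label(np.asarray(mask) > 0, structure=np.ones((3, 3)))
    return int(n)


def measure(result: RepairResult | np.ndarray,
            cfg: PipelineConfig | None = None) -> PhenotypeRecord:
    """Extract the five phenotype traits from a repair result (or raw mask)."""
    cfg = cfg or PipelineConfig()
    if isinstance(result, np.ndarray):
        result = repair(result, cfg)
    skel = result.repaired_skeleton
    mask = result.repaired_mask
    cal = cfg.calibration
    fps = features.extract_feature_points(skel)
    collar = cfg.collar or phenotype.detect_collar(skel)
    rtn = phenotype.root_count(skel, fps, collar, cfg.collar_radius)
    rtl = phenotype.root_length(skel, cal, cfg.diagonal_weighted_length)
    rtw = phenotype.root_width(mask, skel, cal)
    rel = phenotype.extension_length(mask, cal)
    rea = _extension_angle_two_longest(result)
    return PhenotypeRecord(rtn=rtn, rtl_mm=rtl, rtw_mm=rtw, rel_mm=rel,
                           rea_deg=rea)


def _extension_angle_two_longest(result: RepairResult) -> float | None:
    segs = sorted(result.segments, key=lambda s: -s.length_px)
    segs = [s for s in segs if s.length_px >= 2][:2]
    if len(segs) < 2:
        return None
    fits = [fitjoin.fit_polynomial(np.asarray(s.path, float), 1) for s in segs]
    return phenotype.extension_angle(fits[0], fits[1])


def evaluate(result: RepairResult, truth, cfg: PipelineConfig | None = None):
    """Score a repair result against a synthetic ground truth."""
    from .synth import score_recovery

    cfg = cfg or PipelineConfig()
    record = measure(result, cfg)
    measured = {"RTN": record.rtn, "RTL_mm": record.rtl_mm,
                "REL_mm": record.rel_mm}
    return score_recovery(result.repaired_mask, result.joins, truth, measured)
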