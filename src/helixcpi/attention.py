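"""Region attribution from decoder cross-attention weights.

Per pair, the cross-attention tensor (layers x heads x atoms x protein
rows) is averaged over layers, heads and atom queries to a per-position
profile; positions are then grouped by their region provenance. The
per-region score is the mean over that region's real (non-padding)
positions by default, so long regions are not favoured; summing is
available as an option, as is restricting to the final decoder layer.
Test-case level importance is the mean of per-pair region scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .decoder import PredictionResult


@dataclass
class AttentionProfile:
    """Per-protein-position attention mass for one scored pair."""
    weights: np.ndarray                       # (p_max*R,)
    mask: np.ndarray                          # (p_max*R,) True = real position
    provenance: tuple[tuple[str, int], ...]
    pair_id: str = ""


@dataclass
class RegionAttention:
    scores: dict[str, float]
    normalized: bool


def residue_attention(pred: PredictionResult, final_layer_only: bool = False
                      ) -> AttentionProfile:
    """Mean cross-attention each protein position receives.

    Averages over decoder layers (or the last only), heads and atom
    queries; padded positions keep their (~0) mass and are flagged by
    the profile mask.
    """
    if pred.attention is None:
        raise ValueError("prediction was made without retain_attention")
    attn = pred.attention[-1:] if final_layer_only else pred.attention
    weights = attn.mean(axis=(0, 1, 2))
    return AttentionProfile(weights=weights.astype(float), mask=pred.mask,
                            provenance=pred.provenance,
                            pair_id=f"{pred.accession}|{pred.smiles}")


def region_attention(profile: AttentionProfile, mode: str = "mean",
                     normalize: bool = False) -> RegionAttention:
    """Aggregate a profile into per-region importance scores.

    ``mode='mean'`` averages over the region's real positions (default);
    ``mode='sum'`` totals them. With ``normalize=True`` scores are
    rescaled to sum to 1 over regions.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    order: list[str] = []
    groups: dict[str, list[float]] = {}
    for w, valid, (rid, _) in zip(profile.weights, profile.mask, profile.provenance):
        if rid not in groups:
            groups[rid] = []
            order.append(rid)
        if valid:
            groups[rid].append(float(w))
    agg = np.mean if mode == "mean" else np.sum
    scores = {rid: float(agg(groups[rid])) if groups[rid] else 0.0 for rid in order}
    if normalize:
        total = sum(scores.values())
        if total > 0:
            scores = {rid: s / total for rid, s in scores.items()}
    return RegionAttention(scores=scores, normalized=normalize)


def testcase_region_attention(profiles: Sequence[AttentionProfile],
                              mode: str = "mean",
                              normalize: bool = False) -> RegionAttention:
    """Element-wise mean of the per-pair region scores over a pair set."""
    if not profiles:
        raise ValueError("need at least one profile")
    per_pair = [region_attention(p, mode=mode, normalize=normalize) for p in profiles]
    regions: list[str] = []
    for ra in per_pair:
        for rid in ra.scores:
            if rid not in regions:
                regions.append(rid)
    scores = {rid: float(np.mean([ra.scores.get(rid, 0.0) for ra in per_pair]))
              for rid in regions}
    return RegionAttention(scores=scores, normalized=normalize)


def residue_track_rows(profile: AttentionProfile, sequence_lookup=None
                       ) -> list[tuple[int, str, int, bool, float]]:
    """Rows (position, region, within-index, is_real, weight) for CSV export;
    padding positions correspond to the hyphens of a padded-layout plot."""
    return [(i, rid, t, bool(v), float(w))
            for i, ((rid, t), v, w) in enumerate(
                zip(profile.provenance, profile.mask, profile.weights))]


def write_residue_track(profile: AttentionProfile, path) -> None:
    import csv
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "region_id", "within_region_index",
                         "is_real", "weight"])
        writer.writerows(residue_track_rows(profile))


def write_region_summary(region_attn: RegionAttention, path) -> None:
    import json
    payload = {"normalized": region_attn.normalized,
               "scores": region_attn.scores}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def plot_region_attention(region_attn: RegionAttention, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    regions = list(region_attn.scores)
    values = [region_attn.scores[r] for r in regions]
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.bar(regions, values)
    ax.set_ylabel("region attention" + (" (normalized)" if region_attn.normalized else ""))
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
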