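"""Pixel-level reproducibility and agreement statistics for layer boundaries.

The unit of comparison is the per-column absolute difference in boundary
location (dBL, micrometres) between two annotations of the same layer and
frame. From it:

* **inter-grader reproducibility** — dBL averaged over all columns, frames
  and grader pairs of a volume; summarized per layer as mean and sd across
  volumes, together with Lin's concordance correlation of per-volume
  grader-mean layer locations pooled over grader pairs;
* **between-method agreement** — the per-column absolute difference of the
  grader-mean locations of two methods, averaged per volume, with a paired
  two-sided Wilcoxon signed-rank test across volumes.

"Per pixel" means per image column of each B-scan (a boundary has one axial
value per A-scan); aggregation over frames covers the 3-D volume. All
statistics use only columns valid in every compared boundary.

The exact signed-rank distribution (zeros dropped, midranks for ties) is
computed by dynamic programming over doubled ranks, so ties are handled
exactly for small samples; beyond 25 pairs a normal approximation with tie
correction is used.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ComparabilityError, DegenerateInputError, ValidationError
from .io import LAYERS, GraderAnnotationSet, LayerBoundary


def delta_bl(
    a: LayerBoundary, b: LayerBoundary, axial_spacing_um: float
) -> np.ndarray:
    """Per-column absolute boundary-location difference in micrometres.

    Columns not valid in both boundaries carry NaN. Symmetric in its
    arguments. An empty common-valid set produces an all-NaN output with a
    warning rather than an error.
    """
    if a.layer != b.layer or a.frame_index != b.frame_index:
        raise ComparabilityError(
            f"boundaries not comparable: ({a.layer}, frame {a.frame_index}) vs "
            f"({b.layer}, frame {b.frame_index})"
        )
    if a.width != b.width:
        raise ComparabilityError(f"widths differ: {a.width} vs {b.width}")
    common = a.valid_mask & b.valid_mask
    out = np.full(a.width, np.nan)
    out[common] = np.abs(a.positions[common] - b.positions[common]) * axial_spacing_um
    if not common.any():
        warnings.warn("no common valid columns between boundaries", stacklevel=2)
    return out


def concordance_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with population moments.

    ``2*cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))**2)``, all
    moments with 1/n normalization. Undefined (raises) when both variances
    are zero and the means coincide.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValidationError("x and y must be equal-length 1-D with >= 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population (1/n)
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise DegenerateInputError(
            "concordance correlation undefined: zero variance and equal means"
        )
    return float(2.0 * cov / denom)


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def _signed_ranks(diffs: np.ndarray) -> np.ndarray:
    """Midranks of |diffs| (zeros already removed)."""
    a = np.abs(diffs)
    order = np.argsort(a, kind="stable")
    ranks = np.empty(a.size, dtype=np.float64)
    sorted_a = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact p by DP over the 2^n sign assignments, ties included.

    Ranks are doubled to integers; the generating polynomial
    prod(1 + z^(2*r_i)) counts sign patterns per value of 2*W+. The
    two-sided p doubles the smaller tail (capped at 1); the null
    distribution is symmetric, so this equals the enumeration answer.
    """
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for d in doubled:
        counts[d:] += counts[: total + 1 - d]
    n_patterns = 2.0 ** len(ranks)
    w2 = int(round(2.0 * w_plus))
    lower = counts[: w2 + 1].sum() / n_patterns
    upper = counts[w2:].sum() / n_patterns
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(diffs: Sequence[float]) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped; tied absolute differences get midranks.
    Returns ``(W, p)`` with ``W = min(W+, W-)``. Exact distribution for
    n <= 25, normal approximation with tie correction otherwise. All-zero
    input raises :class:`~octseg.errors.DegenerateInputError`.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1 or d.size == 0 or not np.all(np.isfinite(d)):
        raise ValidationError("differences must be a non-empty finite 1-D sequence")
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateInputError("all differences are zero")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = min(w_plus, w_minus)
    n = d.size
    if n <= 25:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        mean = n * (n + 1) / 4.0
        # variance with midrank tie correction
        _, tie_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(((tie_counts**3) - tie_counts).sum()) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        from scipy.stats import norm

        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return statistic, p


# ---------------------------------------------------------------------------
# report containers


@dataclass
class LayerReproducibility:
    mean_um: float
    sd_um: float
    ccc: float  # NaN when undefined (e.g. zero variance)
    per_volume_um: dict[str, float] = field(default_factory=dict)


@dataclass
class ReproducibilityReport:
    """Per-layer inter-grader reproducibility for one method."""

    method: str
    per_layer: dict[str, LayerReproducibility]
    grader_pair_count: int
    volume_ids: tuple[str, ...]
    coverage_fraction: float = 1.0  # share of columns entering the statistics
    ccc_pooling: str = "per-volume grader-mean locations pooled over grader pairs"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "method": self.method,
                "layer": layer,
                "mean_um": rep.mean_um,
                "sd_um": rep.sd_um,
                "concordance_corr": rep.ccc,
            }
            for layer, rep in self.per_layer.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "method": self.method,
            "grader_pair_count": self.grader_pair_count,
            "volume_ids": list(self.volume_ids),
            "coverage_fraction": self.coverage_fraction,
            "ccc_pooling": self.ccc_pooling,
            "per_layer": {
                layer: {
                    "mean_um": rep.mean_um,
                    "sd_um": rep.sd_um,
                    "ccc": None if np.isnan(rep.ccc) else rep.ccc,
                    "per_volume_um": rep.per_volume_um,
                }
                for layer, rep in self.per_layer.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class LayerAgreement:
    mean_um: float
    sd_um: float
    p_value: float
    degenerate: bool
    per_volume_um: dict[str, float] = field(default_factory=dict)


@dataclass
class AgreementReport:
    """Between-method agreement of grader-mean layer locations."""

    per_layer: dict[str, LayerAgreement]
    volume_ids: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "layer": layer,
                "mean_um": rep.mean_um,
                "sd_um": rep.sd_um,
                "p_value": rep.p_value,
                "degenerate": rep.degenerate,
            }
            for layer, rep in self.per_layer.items()
        ]
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "volume_ids": list(self.volume_ids),
            "per_layer": {
                layer: {
                    "mean_um": rep.mean_um,
                    "sd_um": rep.sd_um,
                    "p_value": rep.p_value,
                    "degenerate": rep.degenerate,
                    "per_volume_um": rep.per_volume_um,
                }
                for layer, rep in self.per_layer.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# aggregation


def _spacing_for(
    axial_spacing_um: float | Mapping[str, float], volume_id: str
) -> float:
    if isinstance(axial_spacing_um, Mapping):
        return float(axial_spacing_um[volume_id])
    return float(axial_spacing_um)


def _common_layers_frames(
    sets: Sequence[GraderAnnotationSet],
) -> tuple[tuple[str, ...], tuple[int, ...]]:
    layers = set(sets[0].layers)
    frames = set(sets[0].frame_indices)
    for s in sets[1:]:
        layers &= set(s.layers)
        frames &= set(s.frame_indices)
    return (
        tuple(sorted(layers, key=LAYERS.index)),
        tuple(sorted(frames)),
    )


def inter_grader_reproducibility(
    sets_per_volume: Mapping[str, Sequence[GraderAnnotationSet]],
    axial_spacing_um: float | Mapping[str, float],
) -> ReproducibilityReport:
    """Inter-grader reproducibility of one method across volumes.

    For each layer, the per-volume value is the mean dBL over all columns
    valid in both members of a pair, all frames, and all grader pairs; the
    report carries the mean and (population) sd of these per-volume values
    and the pooled concordance correlation of per-volume grader-mean layer
    locations.
    """
    if not sets_per_volume:
        raise ValidationError("no volumes supplied")
    methods = {s.method for sets in sets_per_volume.values() for s in sets}
    if len(methods) != 1:
        raise ValidationError(f"all sets must share one method, got {methods}")

    n_graders = {len(sets) for sets in sets_per_volume.values()}
    if min(n_graders) < 2:
        raise ValidationError("need at least 2 graders per volume")

    layer_values: dict[str, dict[str, float]] = {}
    ccc_pairs: dict[str, list[tuple[float, float]]] = {}
    pair_count = 0
    covered = 0
    possible = 0
    for volume_id, sets in sets_per_volume.items():
        sets = sorted(sets, key=lambda s: s.grader_id)
        spacing = _spacing_for(axial_spacing_um, volume_id)
        layers, frames = _common_layers_frames(sets)
        pairs = [
            (sets[i], sets[j])
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ]
        pair_count = max(pair_count, len(pairs))
        for layer in layers:
            diffs: list[np.ndarray] = []
            for ga, gb in pairs:
                locs_a: list[np.ndarray] = []
                locs_b: list[np.ndarray] = []
                for f in frames:
                    a, b = ga.get(layer, f), gb.get(layer, f)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        d = delta_bl(a, b, spacing)
                    diffs.append(d[np.isfinite(d)])
                    common = a.valid_mask & b.valid_mask
                    covered += int(common.sum())
                    possible += a.width
                    locs_a.append(a.positions[common] * spacing)
                    locs_b.append(b.positions[common] * spacing)
                xa = np.concatenate(locs_a) if locs_a else np.array([])
                if xa.size:
                    ccc_pairs.setdefault(layer, []).append(
                        (
                            float(np.concatenate(locs_a).mean()),
                            float(np.concatenate(locs_b).mean()),
                        )
                    )
            pooled = np.concatenate(diffs) if diffs else np.array([])
            value = float(pooled.mean()) if pooled.size else np.nan
            layer_values.setdefault(layer, {})[volume_id] = value

    per_layer: dict[str, LayerReproducibility] = {}
    for layer, per_volume in layer_values.items():
        values = np.array(list(per_volume.values()), dtype=np.float64)
        pairs_xy = ccc_pairs.get(layer, [])
        if len(pairs_xy) >= 2:
            x = [p[0] for p in pairs_xy]
            y = [p[1] for p in pairs_xy]
            try:
                ccc = concordance_correlation(x, y)
            except DegenerateInputError:
                ccc = np.nan
        else:
            ccc = np.nan
        per_layer[layer] = LayerReproducibility(
            mean_um=float(np.nanmean(values)),
            sd_um=float(np.nanstd(values)),
            ccc=ccc,
            per_volume_um=dict(per_volume),
        )
    return ReproducibilityReport(
        method=methods.pop(),
        per_layer=per_layer,
        grader_pair_count=pair_count,
        volume_ids=tuple(sets_per_volume.keys()),
        coverage_fraction=(covered / possible) if possible else 0.0,
    )


def method_agreement(
    manual_sets: Mapping[str, Sequence[GraderAnnotationSet]],
    edgeselect_sets: Mapping[str, Sequence[GraderAnnotationSet]],
    axial_spacing_um: float | Mapping[str, float],
) -> AgreementReport:
    """Agreement of grader-mean layer locations between two methods.

    Per column: |mean-over-graders(method A) - mean-over-graders(method B)|,
    using columns valid in every grader of both methods; per-volume value =
    mean over all columns and frames. Across volumes the report carries
    mean, population sd, and a paired two-sided Wilcoxon signed-rank p-value
    on the per-volume *signed* mean location differences. When every
    difference is zero, p is reported as 1 with a degeneracy flag.
    """
    if set(manual_sets) != set(edgeselect_sets):
        raise ValidationError("both methods must cover the same volumes")
    per_layer_vals: dict[str, dict[str, float]] = {}
    per_layer_signed: dict[str, dict[str, float]] = {}
    for volume_id in manual_sets:
        m_sets = sorted(manual_sets[volume_id], key=lambda s: s.grader_id)
        e_sets = sorted(edgeselect_sets[volume_id], key=lambda s: s.grader_id)
        if [s.grader_id for s in m_sets] != [s.grader_id for s in e_sets]:
            raise ValidationError(
                f"grader sets differ between methods for volume {volume_id}"
            )
        spacing = _spacing_for(axial_spacing_um, volume_id)
        layers, frames = _common_layers_frames(list(m_sets) + list(e_sets))
        for layer in layers:
            abs_vals: list[np.ndarray] = []
            signed_vals: list[np.ndarray] = []
            for f in frames:
                bounds_m = [s.get(layer, f) for s in m_sets]
                bounds_e = [s.get(layer, f) for s in e_sets]
                common = np.logical_and.reduce(
                    [b.valid_mask for b in bounds_m + bounds_e]
                )
                if not common.any():
                    continue
                mean_m = np.mean([b.positions[common] for b in bounds_m], axis=0)
                mean_e = np.mean([b.positions[common] for b in bounds_e], axis=0)
                signed = (mean_m - mean_e) * spacing
                abs_vals.append(np.abs(signed))
                signed_vals.append(signed)
            vol_abs = (
                float(np.concatenate(abs_vals).mean()) if abs_vals else np.nan
            )
            vol_signed = (
                float(np.concatenate(signed_vals).mean()) if signed_vals else np.nan
            )
            per_layer_vals.setdefault(layer, {})[volume_id] = vol_abs
            per_layer_signed.setdefault(layer, {})[volume_id] = vol_signed

    per_layer: dict[str, LayerAgreement] = {}
    for layer, per_volume in per_layer_vals.items():
        values = np.array(list(per_volume.values()), dtype=np.float64)
        signed = np.array(list(per_layer_signed[layer].values()), dtype=np.float64)
        signed = signed[np.isfinite(signed)]
        degenerate = bool(signed.size == 0 or np.all(signed == 0))
        if degenerate:
            p = 1.0
        else:
            _, p = wilcoxon_signed_rank(signed)
        per_layer[layer] = LayerAgreement(
            mean_um=float(np.nanmean(values)),
            sd_um=float(np.nanstd(values)),
            p_value=p,
            degenerate=degenerate,
            per_volume_um=dict(per_volume),
        )
    return AgreementReport(
        per_layer=per_layer, volume_ids=tuple(manual_sets.keys())
    )


def reproducibility_comparison(
    manual: ReproducibilityReport, edgeselect: ReproducibilityReport
) -> pd.DataFrame:
    """Per-layer paired Wilcoxon test of manual vs edge-select per-volume
    reproducibility (the scatter-plot comparison, one row per layer)."""
    rows = []
    for layer in manual.per_layer:
        m = manual.per_layer[layer].per_volume_um
        e = edgeselect.per_layer[layer].per_volume_um
        common = sorted(set(m) & set(e))
        diffs = np.array([m[v] - e[v] for v in common])
        try:
            stat, p = wilcoxon_signed_rank(diffs)
        except DegenerateInputError:
            stat, p = np.nan, 1.0
        rows.append(
            {
                "layer": layer,
                "manual_mean_um": manual.per_layer[layer].mean_um,
                "edgeselect_mean_um": edgeselect.per_layer[layer].mean_um,
                "wilcoxon_statistic": stat,
                "p_value": p,
                "n_volumes": len(common),
            }
        )
    return pd.DataFrame(rows)


def scatter_report(
    manual: ReproducibilityReport,
    edgeselect: ReproducibilityReport,
    agreement: AgreementReport | None,
    out_dir: str | Path,
    group_labels: Mapping[str, str] | None = None,
) -> list[Path]:
    """Write per-layer scatter figures.

    One panel per layer: manual vs edge-select per-volume reproducibility
    with the identity line; and, when an agreement report is given, the
    per-volume agreement values with solid mean and dashed mean +/- 2 sd
    lines. Marker fill distinguishes volume groups. Returns written paths;
    an empty report is a no-op with a warning.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    layers = [l for l in LAYERS if l in manual.per_layer and l in edgeselect.per_layer]
    if not layers:
        warnings.warn("empty report; no figures written")
        return written

    def markers_for(volume_ids: Sequence[str]) -> list[str]:
        if not group_labels:
            return ["o"] * len(volume_ids)
        groups = sorted({group_labels.get(v, "") for v in volume_ids})
        cycle = ["o", "s", "^", "D", "v"]
        lut = {g: cycle[i % len(cycle)] for i, g in enumerate(groups)}
        return [lut[group_labels.get(v, "")] for v in volume_ids]

    fig, axes = plt.subplots(1, len(layers), figsize=(4 * len(layers), 4))
    axes = np.atleast_1d(axes)
    for ax, layer in zip(axes, layers):
        m = manual.per_layer[layer].per_volume_um
        e = edgeselect.per_layer[layer].per_volume_um
        vols = sorted(set(m) & set(e))
        marks = markers_for(vols)
        for v, mk in zip(vols, marks):
            ax.scatter(m[v], e[v], marker=mk, color="tab:blue")
        lim = max([m[v] for v in vols] + [e[v] for v in vols] + [1e-6])
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("manual reproducibility (um)")
        ax.set_ylabel("edge-select reproducibility (um)")
        ax.set_title(layer)
    fig.tight_layout()
    path = out_dir / "reproducibility_scatter.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    if agreement is not None and agreement.per_layer:
        fig, axes = plt.subplots(1, len(layers), figsize=(4 * len(layers), 4))
        axes = np.atleast_1d(axes)
        for ax, layer in zip(axes, layers):
            rep = agreement.per_layer[layer]
            vols = sorted(rep.per_volume_um)
            vals = [rep.per_volume_um[v] for v in vols]
            marks = markers_for(vols)
            for i, (v, mk) in enumerate(zip(vols, marks)):
                ax.scatter(i, rep.per_volume_um[v], marker=mk, color="tab:orange")
            mean = float(np.nanmean(vals))
            sd = float(np.nanstd(vals))
            ax.axhline(mean, color="k", lw=1.0)
            ax.axhline(mean + 2 * sd, color="k", lw=0.8, ls="--")
            ax.axhline(mean - 2 * sd, color="k", lw=0.8, ls="--")
            ax.set_xlabel("volume")
            ax.set_ylabel("|manual - edge-select| (um)")
            ax.set_title(layer)
        fig.tight_layout()
        path = out_dir / "agreement_scatter.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
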