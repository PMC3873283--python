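"""In-silico reading-center study: phantoms, simulated graders, statistics.

Mirrors the design of a multi-grader OCT segmentation study at desk scale:
a set of random phantoms is annotated by several simulated graders with both
the manual (spline) and the interactive edge-select method, and the
inter-grader reproducibility of each method plus the between-method
agreement are computed per layer.

The study runs on 224x288-pixel single-frame phantoms (geometry scaled from
the full 496x512 default) so the whole pipeline stays fast enough for
routine re-runs; the statistics are identical in structure to those a
full-size volume study would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .edges import LayerProfile, default_profiles
from .io import GraderAnnotationSet, OCTVolume
from .metrics import (
    AgreementReport,
    ReproducibilityReport,
    inter_grader_reproducibility,
    method_agreement,
    reproducibility_comparison,
)
from .pathing import CostParams
from .phantom import GraderModel, generate_volume, random_phantom_spec, simulate_grader

STUDY_SHAPE = (224, 288)


@dataclass
class StudyResult:
    manual: ReproducibilityReport
    edgeselect: ReproducibilityReport
    agreement: AgreementReport
    manual_sets: dict[str, list[GraderAnnotationSet]] = field(default_factory=dict)
    edgeselect_sets: dict[str, list[GraderAnnotationSet]] = field(default_factory=dict)
    truth_sets: dict[str, GraderAnnotationSet] = field(default_factory=dict)
    volumes: dict[str, OCTVolume] = field(default_factory=dict)
    axial_spacing_um: float = 3.87

    def comparison(self):
        """Per-layer paired Wilcoxon of manual vs edge-select reproducibility."""
        return reproducibility_comparison(self.manual, self.edgeselect)


def run_insilico_study(
    seed: int,
    n_phantoms: int = 12,
    n_graders: int = 3,
    shape: tuple[int, int] = STUDY_SHAPE,
    speckle_variance: float = 1.0 / 9.0,
    manual_model: GraderModel | None = None,
    edgeselect_model: GraderModel | None = None,
    profiles: Mapping[str, LayerProfile] | None = None,
    params: CostParams = CostParams(),
) -> StudyResult:
    """Run the full in-silico study and return its reports.

    Deterministic for a fixed seed: every phantom and grader draws from a
    sub-seed derived from ``seed`` via a SeedSequence spawn.
    """
    manual_model = manual_model or GraderModel(kind="manual")
    edgeselect_model = edgeselect_model or GraderModel(kind="edgeselect")
    profiles = dict(profiles or default_profiles())

    root = np.random.SeedSequence(seed)
    phantom_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_phantoms)]
    grader_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in root.spawn(2 * n_phantoms * n_graders)
    ]

    manual_sets: dict[str, list[GraderAnnotationSet]] = {}
    edge_sets: dict[str, list[GraderAnnotationSet]] = {}
    truth_sets: dict[str, GraderAnnotationSet] = {}
    volumes: dict[str, OCTVolume] = {}
    spacing: dict[str, float] = {}
    for p, pseed in enumerate(phantom_seeds):
        spec = random_phantom_spec(
            pseed, shape=shape, speckle_variance=speckle_variance
        )
        volume, truth = generate_volume(spec, n_frames=1)
        volumes[volume.volume_id] = volume
        truth_sets[volume.volume_id] = truth
        spacing[volume.volume_id] = volume.axial_spacing_um
        manual_sets[volume.volume_id] = []
        edge_sets[volume.volume_id] = []
        for g in range(n_graders):
            base = 2 * (p * n_graders + g)
            gseed_m, gseed_e = grader_seeds[base], grader_seeds[base + 1]
            manual_sets[volume.volume_id].append(
                simulate_grader(
                    volume,
                    truth,
                    manual_model,
                    gseed_m,
                    grader_id=f"g{g + 1}",
                    profiles=profiles,
                    params=params,
                )
            )
            edge_sets[volume.volume_id].append(
                simulate_grader(
                    volume,
                    truth,
                    edgeselect_model,
                    gseed_e,
                    grader_id=f"g{g + 1}",
                    profiles=profiles,
                    params=params,
                )
            )

    manual_report = inter_grader_reproducibility(manual_sets, spacing)
    edge_report = inter_grader_reproducibility(edge_sets, spacing)
    agreement = method_agreement(manual_sets, edge_sets, spacing)
    return StudyResult(
        manual=manual_report,
        edgeselect=edge_report,
        agreement=agreement,
        manual_sets=manual_sets,
        edgeselect_sets=edge_sets,
        truth_sets=truth_sets,
        volumes=volumes,
    )
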