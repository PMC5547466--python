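"""End-to-end per-nucleus analysis and batch driver.

Chains the stages: nuclear mask from DAPI -> HMRF compaction
classification -> per-channel spot segmentation -> cross-channel pairing
filter -> class profiles, enrichment profiles, neighbor matrix and
minimal class distances.  Results are plain dataclasses; the writer
functions emit CSV tables, TIFF label/heat maps and a JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassMap, MixtureParams, class_fractions, classify_hmrf
from .io import (
    ImageStack,
    NucleusMask,
    PipelineConfig,
    export_heatmap,
    read_stack,
    write_mask,
    write_stack,
)
from .nucleus import segment_nucleus
from .spots import SpotSet, pair_filter, segment_spots
from .topography import (
    ClassProfile,
    EnrichmentProfile,
    MinDistTable,
    NeighborMatrix,
    enrichment_profile,
    min_class_distances,
    neighbor_class_matrix,
    spot_class_distribution,
)


@dataclass
class NucleusResult:
    """All per-nucleus outputs of the mapping pipeline."""

    nucleus_id: str
    mask: NucleusMask
    class_map: ClassMap
    params: MixtureParams
    dapi_profile: ClassProfile
    spots: dict[str, SpotSet]            # retained spots per channel
    discarded: dict[str, SpotSet]        # background-filtered spots
    signal_profiles: dict[str, ClassProfile]
    enrichments: dict[str, EnrichmentProfile]
    neighbor_matrix: NeighborMatrix
    min_dist_class2: MinDistTable | None


def analyze_nucleus(
    dapi: ImageStack,
    ch1: ImageStack,
    ch2: ImageStack,
    config: PipelineConfig,
    nucleus_id: str = "nucleus",
    mask: NucleusMask | None = None,
) -> NucleusResult:
    """Run the full mapping workflow on one nucleus.

    A precomputed mask may be supplied (e.g. a phantom's ground-truth
    mask); otherwise it is segmented from the DAPI channel.
    """
    if mask is None:
        mask = segment_nucleus(
            dapi, sigma_nm=config.mask_sigma_nm,
            min_fraction=config.min_mask_fraction,
        )
    work = dapi
    if config.rescale_dapi:
        vals = dapi.voxels[mask.member]
        lo, hi = float(vals.min()), float(vals.max())
        scaled = np.clip((dapi.voxels - lo) / max(hi - lo, 1e-12), 0, None)
        work = ImageStack(scaled, dapi.spacing, dapi.channel_name)

    class_map, params = classify_hmrf(
        work, mask, n_classes=config.n_classes, beta=config.potts_beta,
        seed=config.seed, max_iter=config.max_iter, tol=config.tol,
        use_pi=config.use_pi,
    )
    dapi_profile = class_fractions(class_map, mask)
    dapi_profile.nucleus_id = nucleus_id

    raw = {}
    for ch in (ch1, ch2):
        s = segment_spots(
            ch, mask, k_sd=config.k_sd, min_voxels=config.min_voxels,
            relative_floor=config.relative_floor,
        )
        s.nucleus_id = nucleus_id
        raw[ch.channel_name] = s
    names = list(raw)
    kept_a, kept_b, (lost_a, lost_b) = pair_filter(
        raw[names[0]], raw[names[1]], max_dist_nm=config.pairing_max_dist_nm
    )
    spots = {names[0]: kept_a, names[1]: kept_b}
    discarded = {names[0]: lost_a, names[1]: lost_b}

    signal_profiles = {}
    enrichments = {}
    for name, ss in spots.items():
        if ss.spots:
            prof = spot_class_distribution(ss, class_map, weighting="intensity")
            signal_profiles[name] = prof
            enrichments[name] = enrichment_profile(prof, dapi_profile)

    nbm = neighbor_class_matrix(class_map, mask)
    mind = None
    if (class_map.labels == 2).any():
        mind = min_class_distances(class_map, 2, config.spacing)

    return NucleusResult(
        nucleus_id, mask, class_map, params, dapi_profile, spots,
        discarded, signal_profiles, enrichments, nbm, mind,
    )


def _spots_frame(result: NucleusResult) -> pd.DataFrame:
    rows = []
    for retained, group in ((True, result.spots), (False, result.discarded)):
        for name, ss in group.items():
            for s in ss.spots:
                cz, cy, cx = s.centroid_nm
                rows.append(
                    (result.nucleus_id, name, cz, cy, cx, s.volume_um3,
                     s.n_voxels, retained)
                )
    return pd.DataFrame(
        rows,
        columns=["nucleus_id", "channel", "cz_nm", "cy_nm", "cx_nm",
                 "volume_um3", "n_voxels", "retained"],
    )


def write_results(result: NucleusResult, out_dir: str | Path,
                  config: PipelineConfig) -> None:
    """Write one nucleus' tables, label map and heat map to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = result.class_map.n_classes
    cls_cols = [f"class_{i}" for i in range(1, k + 1)]

    write_mask(result.mask, out / "mask.tif")
    import tifffile

    tifffile.imwrite(out / "classes.tif", result.class_map.labels)
    export_heatmap(result.class_map, out / "heatmap.tif")

    prof_rows = [
        [result.nucleus_id, "dapi", *result.dapi_profile.fractions]
    ]
    for name, p in result.signal_profiles.items():
        prof_rows.append([result.nucleus_id, name, *p.fractions])
    pd.DataFrame(
        prof_rows, columns=["nucleus_id", "source", *cls_cols]
    ).to_csv(out / "class_profiles.csv", index=False, float_format="%.10g")

    enr_rows = [
        [result.nucleus_id, name, *e.points]
        for name, e in result.enrichments.items()
    ]
    pd.DataFrame(
        enr_rows, columns=["nucleus_id", "channel", *cls_cols]
    ).to_csv(out / "enrichment.csv", index=False, float_format="%.10g")

    _spots_frame(result).to_csv(
        out / "spots.csv", index=False, float_format="%.10g"
    )

    pd.DataFrame(
        result.neighbor_matrix.matrix,
        index=[f"class_{i}" for i in range(1, k + 1)],
        columns=cls_cols,
    ).to_csv(out / "neighbor_matrix.csv", float_format="%.10g")

    if result.min_dist_class2 is not None:
        pd.DataFrame(
            {
                "target_class": np.arange(1, k + 1),
                "mean_nm": result.min_dist_class2.mean_nm,
                "sd_nm": result.min_dist_class2.sd_nm,
            }
        ).to_csv(out / "min_dist_class2.csv", index=False,
                 float_format="%.10g")

    summary = {
        "nucleus_id": result.nucleus_id,
        "mask_voxels": result.mask.n_voxels,
        "mask_flagged": bool(result.mask.flagged),
        "mixture_mu": [float(v) for v in result.params.mu],
        "mixture_sigma2": float(result.params.sigma2),
        "mixture_pi": [float(v) for v in result.params.pi],
        "potts_beta": float(result.params.beta),
        "converged": bool(result.params.converged),
        "n_iter": int(result.params.n_iter),
        "retained_spots": {n: len(s) for n, s in result.spots.items()},
        "discarded_spots": {n: len(s) for n, s in result.discarded.items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)


def run_pipeline(
    config: PipelineConfig,
    dapi_path: str | Path,
    ch1_path: str | Path,
    ch2_path: str | Path,
    out_dir: str | Path,
    nucleus_id: str = "nucleus",
) -> NucleusResult:
    """File-to-file driver: read three channels, analyze, write results."""
    dapi = read_stack(dapi_path, "dapi", config.spacing, config.channel_index)
    ch1 = read_stack(ch1_path, "ch1", config.spacing, config.channel_index)
    ch2 = read_stack(ch2_path, "ch2", config.spacing, config.channel_index)
    result = analyze_nucleus(dapi, ch1, ch2, config, nucleus_id)
    write_results(result, out_dir, config)
    return result
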