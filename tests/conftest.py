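"""Shared fixtures: desk-scale synthetic ensembles processed end to end.

The expensive session fixtures run the full boundary -> conformal ->
Mobius -> Radon pipeline once and are shared by the end-to-end and
acceptance tests.  Problem sizes (image raster, polygon order, disc
diameter, Radon step) are reduced relative to the library defaults; the
methods note documents the choices.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from discmorph.alignment import SearchGrid
from discmorph.pipeline import PipelineConfig, process_ensemble, process_wing
from discmorph.radon import ensemble_to_matrix
from discmorph.synthetic import (
    VariationSpec,
    WingTemplate,
    generate_ensemble,
    latent_mode_pair,
)

SMALL_SHAPE = (240, 320)

# group offsets along the latent mode, in units of the orthogonal noise
# scale sigma_orth (the generator converts them to latent-score shifts)
CYL_OFFSETS = {"c2": (2.0, 0.0), "c5": (5.0, 0.0), "c10": (10.0, 0.0), "c20": (20.0, 0.0)}


def small_config() -> PipelineConfig:
    return PipelineConfig(
        disc_diameter=100,
        n_vertices=32,
        radon_step_deg=2.0,
        search=SearchGrid(n_refine=3),
    )


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    return small_config()


@pytest.fixture(scope="session")
def wing_template() -> WingTemplate:
    return WingTemplate()


@pytest.fixture(scope="session")
def base_spec() -> VariationSpec:
    return VariationSpec()


@pytest.fixture(scope="session")
def single_wing(wing_template, base_spec):
    from discmorph.synthetic import generate_wing

    return generate_wing(wing_template, base_spec, t=0.5, shape=SMALL_SHAPE, seed=11)


@pytest.fixture(scope="session")
def single_disc(single_wing, small_cfg):
    return process_wing(
        single_wing.image, single_wing.mask, single_wing.anchors, small_cfg,
        image_id=single_wing.image_id,
    )


@pytest.fixture(scope="session")
def big_run(wing_template, small_cfg):
    """The main end-to-end run: one latent axis, n=100 reference group plus
    four groups displaced along the mode at increasing distances."""
    # groups of unequal size: generate each separately, then merge
    from discmorph.synthetic import WingDataset
    import pandas as pd

    # displaced probe groups: offsets in sigma_orth units, with their own
    # latent spread suppressed so the centroid distance R is controlled
    spec_wt = VariationSpec(
        group_offsets=CYL_OFFSETS,
        latent_sigma_scale={g: 0.1 for g in CYL_OFFSETS},
    )
    parts = []
    sizes = {"wt": 100, "c2": 24, "c5": 24, "c10": 24, "c20": 24}
    for gi, (g, n) in enumerate(sizes.items()):
        parts.append(
            generate_ensemble(
                wing_template, spec_wt, n, [g], seed=101 + gi, shape=SMALL_SHAPE
            )
        )
    ds = WingDataset(
        samples=[s for p in parts for s in p.samples],
        manifest=pd.concat([p.manifest for p in parts], ignore_index=True),
        template=wing_template,
        spec=spec_wt,
        truth=parts[0].truth,
    )
    ens, matrix = process_ensemble(ds, small_cfg, reference_id="wt_0000")
    return ds, ens, matrix


def estimate_planted_mode(template, spec, cfg, reference_image, delta=1.0,
                          seeds=(7, 8, 9), shape=SMALL_SHAPE):
    """Ground-truth latent-mode direction in Radon phenotype space.

    Nuisance-free wing pairs at t = +-delta are pushed through the
    identical pipeline, registered to the run's reference, differenced and
    averaged over texture seeds.  Staying at small delta keeps the pair
    within the quasi-linear response regime of the intensity
    representation; averaging suppresses registration noise.
    """
    from discmorph.alignment import register_to_reference
    from discmorph.radon import radon_transform

    vecs = []
    for sd in seeds:
        lo, hi = latent_mode_pair(template, spec, delta=delta, shape=shape, seed=sd)
        rows = []
        for s in (lo, hi):
            disc = process_wing(s.image, s.mask, s.anchors, cfg, image_id=s.image_id)
            _, aligned, _ = register_to_reference(disc, reference_image, cfg.search)
            rows.append(radon_transform(aligned, cfg.angles()).flatten())
        v = rows[1] - rows[0]
        vecs.append(v / np.linalg.norm(v))
    mode = np.mean(vecs, axis=0)
    return mode / np.linalg.norm(mode)


@pytest.fixture(scope="session")
def planted_mode_vector(wing_template, base_spec, small_cfg, big_run):
    _, ens, matrix = big_run
    ref = next(im for im in ens.images if im.provenance["image_id"] == ens.reference_id)
    return estimate_planted_mode(wing_template, base_spec, small_cfg, ref)


@pytest.fixture(scope="session")
def perturbation_runs(wing_template, small_cfg):
    """Baseline plus origin/anchor/boundary-jitter reruns of a two-group set."""
    from discmorph.synthetic import WingDataset, apply_pipeline_perturbations
    import pandas as pd

    spec = VariationSpec(group_offsets={"mut": (20.0, 0.0)},
                         latent_sigma_scale={"mut": 0.1})
    a = generate_ensemble(wing_template, spec, 20, ["wt"], seed=301, shape=SMALL_SHAPE)
    b = generate_ensemble(wing_template, spec, 20, ["mut"], seed=302, shape=SMALL_SHAPE)
    ds = WingDataset(
        samples=a.samples + b.samples,
        manifest=pd.concat([a.manifest, b.manifest], ignore_index=True),
        template=wing_template,
        spec=spec,
        truth=a.truth,
    )
    runs = {"baseline": process_ensemble(ds, small_cfg, reference_id="wt_0000")}
    for mode in ("origin_jitter", "anchor_jitter", "boundary_jitter"):
        pert = apply_pipeline_perturbations(ds, mode, seed=17)
        runs[mode] = process_ensemble(pert, small_cfg, reference_id="wt_0000")
    return runs
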