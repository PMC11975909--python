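"""Shared fixtures: small rendered wells and a truth-labeled detection set.

Everything is generated programmatically at session start; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenoscreen import pipeline as pl
from phenoscreen import synthetic as syn
from phenoscreen.segmentation import SegmentationParams


def make_layout_row(condition="DMSO", timepoint=24.0, donor="d01",
                    plate="P01", well="A01", cohort="HV") -> pd.Series:
    return pd.Series({
        "plate_id": plate, "well_id": well, "field_index": 0,
        "condition": condition, "concentration": 0.0,
        "concentration_unit": "uM", "timepoint_h": timepoint,
        "donor_id": donor, "cohort": cohort,
    })


@pytest.fixture(scope="session")
def render_params() -> syn.RenderParams:
    return syn.RenderParams()


@pytest.fixture(scope="session")
def seg_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def rendered_well(render_params):
    """One default 40-cell well: (truth, field image)."""
    truth = syn.simulate_well(make_layout_row(), syn.EffectSpec(), 40, seed=11)
    field = syn.render_field(truth, 0, render_params, seed=12)
    return truth, field


@pytest.fixture(scope="session")
def training_data(render_params, seg_params):
    """Truth-labeled detections from phenotype-enriched wells.

    Returns (cells, embeddings): generator truth rows for matched detections
    and their descriptor vectors, row-aligned — the stand-in for a
    hand-labeled example set.
    """
    return pl.build_training_set(render_params, seg_params, seed=5,
                                 n_wells=12, cells_per_well=80)


def single_cell_embeddings(state: str, n: int, seed0: int,
                           field_px: int = 128) -> np.ndarray:
    """Embeddings of isolated rendered small round cells forced into one
    actin state ("contracted" | "dispersed" | "unstained")."""
    from phenoscreen import featurization as feat
    from phenoscreen.segmentation import detect_cells

    base = syn.PhenotypeBaseline(
        large_frac=0.0, annexin=0.0, fragmented=0.0,
        actin_stained=0.0 if state == "unstained" else 1.0,
        contracted_given_stained=1.0 if state == "contracted" else 0.0)
    spec = syn.EffectSpec(baseline=base, donor_sd=0.0)
    out = []
    i = 0
    while len(out) < n:
        truth = syn.simulate_well(make_layout_row(), spec, 1,
                                  seed=seed0 * 100_000 + i)
        fld = syn.render_field(truth, 0, syn.RenderParams(field_px=field_px),
                               seed=seed0 * 200_000 + i)
        _, crops = detect_cells(fld)
        if len(crops) == 1:
            out.append(feat.embed(crops[0]).vector)
        i += 1
    return np.array(out)
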