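"""Shared fixtures: small phantoms for unit tests and one session-scoped run
of the five-segment reference fixture for the end-to-end checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from xylotrace.classify import classify_gallery
from xylotrace.morphometry import measure_all
from xylotrace.phantom import PhantomConfig, generate_phantom, truth_mask
from xylotrace.segment import segment_volume

warnings.filterwarnings("ignore", message="tube extends beyond")


@pytest.fixture(scope="session")
def small_phantom():
    """A 9 cm / 120-slice phantom with 2 C + 1 S + 1 Y galleries."""
    cfg = PhantomConfig(
        trunk_diameter_mm=90.0,
        n_slices=120,
        counts={"C": 2, "S": 1, "Y": 1},
        seed=7,
    )
    volume, truths, ring = generate_phantom(cfg)
    return cfg, volume, truths, ring


@pytest.fixture(scope="session")
def small_truth_mask(small_phantom):
    cfg, _, truths, ring = small_phantom
    return truth_mask(truths, cfg, ring)


@pytest.fixture(scope="session")
def small_segmented(small_phantom):
    _, volume, _, _ = small_phantom
    return segment_volume(volume)


def _match_labels(gm, tlab, n_truth):
    """recovered label -> truth index by maximum voxel overlap."""
    out = {}
    for r in gm.label_ids():
        rm = gm.labels == r
        ov = [int((rm & (tlab == k)).sum()) for k in range(1, n_truth + 1)]
        out[r] = int(np.argmax(ov)) + 1
    return out


@pytest.fixture(scope="session")
def small_measured(small_phantom, small_segmented):
    _, volume, _, _ = small_phantom
    metrics, centerlines, pith = measure_all(volume, small_segmented)
    return metrics, centerlines, pith


@pytest.fixture(scope="session")
def fixture_run():
    """The packaged five-segment fixture (43 galleries, 36 C / 3 S / 4 Y)
    pushed through the full pipeline at default parameters.

    Shared across the end-to-end acceptance-style tests because it is the
    expensive part of the suite.
    """
    from xylotrace.phantom import default_fixture_configs

    per_volume = []
    for cfg in default_fixture_configs(seed=1):
        volume, truths, ring = generate_phantom(cfg)
        gm = segment_volume(volume)
        metrics, centerlines, pith = measure_all(volume, gm)
        calls = {
            m.label: classify_gallery(
                centerlines[m.label], m.vertical_length_mm, label=m.label
            )
            for m in metrics
        }
        tlab, tblk = truth_mask(truths, cfg, ring)
        match = _match_labels(gm, tlab, len(truths))
        per_volume.append(
            dict(
                cfg=cfg,
                truths=truths,
                ring=ring,
                mask=gm,
                metrics=metrics,
                centerlines=centerlines,
                calls=calls,
                tlab=tlab,
                tblk=tblk,
                match=match,
            )
        )
    return per_volume
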