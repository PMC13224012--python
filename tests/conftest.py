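import numpy as np
import pandas as pd
import pytest

from mitohicp import simgen


@pytest.fixture(scope="session")
def compact_geometry():
    """Small-field geometry used throughout the suite to keep renders fast;
    same noise model as the default geometry."""
    return simgen.default_geometry(
        image_size=256, nucleus_radius=(5, 7), cell_radius=(11, 15),
        mito_count=(5, 9), mito_segment_length=(6, 12),
    )


@pytest.fixture(scope="session")
def noiseless_geometry():
    return simgen.default_geometry(
        image_size=256, nucleus_radius=(5, 7), cell_radius=(11, 15),
        mito_count=(5, 9), mito_segment_length=(6, 12),
        background_level=0.0, poisson_gain=0.0, read_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def control_spec():
    """Normal-line baseline group: rho(M,S)=0.75 > rho(M,R)=0.35."""
    return simgen.make_group("HPFC", "control")


@pytest.fixture(scope="session")
def rendered_field(control_spec, compact_geometry):
    latents = simgen.sample_latents(control_spec, 20, seed=41)
    stack, gt = simgen.render_field(latents, compact_geometry, seed=42)
    return stack, gt


@pytest.fixture(scope="session")
def segmented_field(rendered_field):
    from mitohicp import segment

    stack, gt = rendered_field
    maps = segment.segment_field(stack, max_cell_distance=8)
    return stack, gt, maps


def integer_latents(values):
    """Hand-built latent table with integer-friendly amplitudes so that the
    noiseless renderer produces exactly integral pixel values."""
    rows = [
        {"cell_id": i + 1, "M": m, "R": r, "S": s}
        for i, (m, r, s) in enumerate(values)
    ]
    return pd.DataFrame(rows, columns=["cell_id", "M", "R", "S"])


def match_objects(truth: np.ndarray, pred: np.ndarray):
    """Greedy one-to-one matching of label maps by IoU; returns the list of
    matched IoUs plus counts of unmatched truth/pred objects."""
    t_ids = [t for t in np.unique(truth) if t > 0]
    p_ids = [p for p in np.unique(pred) if p > 0]
    pairs = []
    for t in t_ids:
        tm = truth == t
        for p in p_ids:
            pm = pred == p
            inter = np.logical_and(tm, pm).sum()
            if inter:
                union = np.logical_or(tm, pm).sum()
                pairs.append((inter / union, t, p))
    pairs.sort(reverse=True)
    used_t, used_p, ious = set(), set(), []
    for iou, t, p in pairs:
        if t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        ious.append(iou)
    return ious, len(t_ids) - len(used_t), len(p_ids) - len(used_p)
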