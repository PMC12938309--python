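"""Shared fixtures: default geometry and cached synthesis round trips."""

import numpy as np
import pytest

import cturnkit as ck
from cturnkit.kinematics import mask_centroid_track

_ROUNDTRIP_CACHE = {}


@pytest.fixture(scope="session")
def geometry():
    return ck.BodyGeometry()


def _roundtrip(name: str) -> dict:
    """Synthesize a packaged maneuver, extract midlines, cache everything."""
    if name not in _ROUNDTRIP_CACHE:
        tpl = ck.maneuver_template(name)
        fld, pose, seq = ck.synthesize_maneuver(tpl)
        midlines, masks, report = ck.extract_midlines(seq)
        centroid = mask_centroid_track(masks, seq.scale)
        _ROUNDTRIP_CACHE[name] = {
            "template": tpl,
            "field": fld,
            "pose": pose,
            "seq": seq,
            "midlines": midlines,
            "masks": masks,
            "report": report,
            "centroid": centroid,
            "truth": ck.fixture_truth(name),
        }
    return _ROUNDTRIP_CACHE[name]


@pytest.fixture(scope="session")
def roundtrip():
    """Callable fixture: roundtrip('turn_large') -> cached pipeline outputs."""
    return _roundtrip


@pytest.fixture(scope="session")
def straight_sequence(geometry):
    """A straight gliding body (zero curvature, constant heading)."""
    tpl = ck.maneuver_template("turn_small", psi0=0.0, psiT=0.0, A=0.0,
                               u0_frac=0.1)
    fld = ck.make_cturn_curvature(tpl)
    pose = ck.make_pose_track(tpl)
    seq = ck.render_silhouette(fld, pose, geometry, ck.ImageConfig())
    return tpl, fld, pose, seq


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
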