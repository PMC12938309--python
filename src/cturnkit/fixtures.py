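"""Packaged representative maneuvers.

Three synthetic C-turn templates spanning the small / mid / large yaw range
(67.0, 108.8 and 156.3 deg), with prescribed heading tracks whose total
turn equals the nominal angle exactly, so they serve as round-trip ground
truth for the render -> extract -> measure pipeline.  The curvature
amplitude is held near the physiological ceiling across fixtures while the
bump width grows with the turn angle — larger turns bend more of the body,
not the same segment harder.
"""

from __future__ import annotations

from .synthetic import ManeuverTemplate

__all__ = ["FIXTURES", "maneuver_template", "fixture_truth"]

# headings are symmetric about zero so the maneuver footprint stays compact
FIXTURES = {
    "turn_small": dict(psi0=-33.5, psiT=33.5, T=0.224, A=5.5,
                       bump_width=0.085, u0_frac=0.12),
    "turn_mid": dict(psi0=-54.4, psiT=54.4, T=0.210, A=5.8,
                     bump_width=0.125, u0_frac=0.15),
    "turn_large": dict(psi0=-78.15, psiT=78.15, T=0.195, A=6.0,
                       bump_width=0.175, u0_frac=0.30),
}


def maneuver_template(name: str, **overrides) -> ManeuverTemplate:
    """Packaged maneuver template by name ('turn_small'/'turn_mid'/'turn_large')."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    params = dict(FIXTURES[name])
    params.update(overrides)
    return ManeuverTemplate(**params)


def fixture_truth(name: str) -> dict:
    """Ground-truth quantities of a packaged fixture (exact by prescription)."""
    p = FIXTURES[name]
    return {"phi": abs(p["psiT"] - p["psi0"]), "T": p["T"], "A": p["A"],
            "u0": p["u0_frac"]}
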