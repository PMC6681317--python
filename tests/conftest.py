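"""Shared fixtures: example roots, random-root strategies, RSML builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import strategies as st

from rhizochron import RootSystem

# hypothesis is run seeded/derandomised via the profile in each test module;
# lengths are kept on the mm scale of real seedling tracings
finite_len = st.floats(min_value=0.0, max_value=200.0, allow_nan=False, allow_infinity=False)
positive_len = st.floats(min_value=0.01, max_value=200.0, allow_nan=False, allow_infinity=False)


@st.composite
def root_systems(draw, max_lr: int = 12) -> RootSystem:
    """Random valid RootSystem with 0..max_lr lateral roots."""
    n = draw(st.integers(min_value=0, max_value=max_lr))
    segments = tuple(draw(st.lists(finite_len, min_size=n, max_size=n)))
    lrs = tuple(draw(st.lists(finite_len, min_size=n, max_size=n)))
    tip = draw(positive_len)
    return RootSystem("hyp", "acc", 8, "", segments, tip, lrs)


@pytest.fixture
def two_lr_root() -> RootSystem:
    """The worked example: LRs of 5 and 3 mm at positions 10 and 20 mm."""
    return RootSystem("p1", "Col-0", 8, "", (10.0, 10.0), 5.0, (5.0, 3.0))


def random_fittable_root(rng: np.random.Generator, max_lr: int = 50) -> RootSystem:
    """Random root with 2..max_lr LRs at distinct positions (for OLS checks)."""
    n = int(rng.integers(2, max_lr + 1))
    positions = np.sort(rng.uniform(1.0, 80.0, n))
    while np.unique(positions).size < 2:
        positions = np.sort(rng.uniform(1.0, 80.0, n))
    segments = np.diff(positions, prepend=0.0)
    lengths = rng.uniform(0.0, 15.0, n)
    return RootSystem("rnd", "acc", 10, "", tuple(segments), float(rng.uniform(1, 30)), tuple(lengths))


def build_rsml(plants: list[dict], origin_x: float = 0.0) -> str:
    """Serialise plants into a minimal RSML document.

    Each plant dict has ``id``, ``label``, ``pr_length`` and ``laterals`` --
    a list of (insertion_position, lr_length) pairs.  Primary roots run along
    the y axis with a polyline vertex at every insertion point; laterals run
    along x from their insertion point, so all arc lengths are exact.
    """
    chunks = ['<?xml version="1.0" encoding="UTF-8"?>', "<rsml><scene>"]
    for plant in plants:
        chunks.append(f'<plant id="{plant["id"]}" label="{plant.get("label", "")}">')
        laterals = plant.get("laterals", [])
        vertices = [0.0] + [pos for pos, _ in laterals] + [plant["pr_length"]]
        pts = "".join(f'<point x="{origin_x}" y="{v}"/>' for v in dict.fromkeys(vertices))
        chunks.append(f'<root id="{plant["id"]}_pr"><geometry><polyline>{pts}</polyline></geometry>')
        for k, (pos, length) in enumerate(laterals, start=1):
            chunks.append(
                f'<root id="{plant["id"]}_lr{k}"><geometry><polyline>'
                f'<point x="{origin_x}" y="{pos}"/><point x="{origin_x + length}" y="{pos}"/>'
                "</polyline></geometry></root>"
            )
        chunks.append("</root></plant>")
    chunks.append("</scene></rsml>")
    return "".join(chunks)


def measurement_csv(rows: list[tuple]) -> str:
    """Build a measurement-table CSV from (plant, acc, day, trt, type, idx, mm) rows."""
    header = "plant_id,accession,day,treatment,record_type,order_index,length_mm"
    return "\n".join([header] + [",".join(str(v) for v in r) for r in rows]) + "\n"
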