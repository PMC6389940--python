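"""Candidate admixture-graph family for the five wild-yeast lineages.

Fifteen five-population models over SpA (outgroup), SpB, SpC, SpC* and SpD:
plain trees, single-admixture graphs and two-admixture graphs, including
the two shapes in which SpD itself is admixed — M01 (SpD from a SpB x SpC*
backcross, with SpC* itself a SpB x SpC hybrid) and M02 (SpD from an early
SpB x SpC cross predating the SpC* hybrid).  The family is shipped both as
builder code and as an editable JSON file (``data/models.json``); edge
lengths in the candidates are placeholders — fitting treats them as free.

Graphs are kept minimally parameterized (stems subdivided only where an
admixture source needs an intermediate node): distinct-population f4
statistics on five populations span only a 5-dimensional space, so extra
free internal edges would make mixing proportions unidentifiable.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .popgen import AdmixtureGraph

__all__ = ["candidate_models", "m01_graph", "load_models", "save_models", "POPULATIONS"]

POPULATIONS = ["SpA", "SpB", "SpC", "SpC*", "SpD"]

_L = 0.01  # placeholder drift length for candidate models

# shared backbone: root R, SpA outgroup, BC ancestor, B and C stems
_BACKBONE = [
    ("R", "SpA"),
    ("R", "BC"),
    ("BC", "B1"),
    ("B1", "SpB"),
    ("BC", "C1"),
    ("C1", "SpC"),
]

_LEAVES = {"SpA": "SpA", "SpB": "SpB", "SpC": "SpC", "SpC*": "SpC*", "SpD": "SpD"}


def _graph(model_id, extra_edges, admixture, backbone=_BACKBONE):
    edges = {e: _L for e in backbone}
    edges.update({e: _L for e in extra_edges})
    return AdmixtureGraph(model_id, edges, admixture, dict(_LEAVES))


# backbone with subdivided stems, for models whose admixture happens "late"
_BACKBONE_DEEP = [
    ("R", "SpA"),
    ("R", "BC"),
    ("BC", "B1"),
    ("B1", "B2"),
    ("B2", "SpB"),
    ("BC", "C1"),
    ("C1", "C2"),
    ("C2", "SpC"),
]


def candidate_models() -> list[AdmixtureGraph]:
    """The 15-model candidate set, ids M01..M15."""
    models = [
        # --- two admixture events -----------------------------------------
        # M01: SpC* = SpB x SpC hybrid; SpD = backcross of SpB with SpC*
        _graph(
            "M01",
            [("CsM", "Cs1"), ("Cs1", "SpC*"), ("DM", "SpD")],
            {"CsM": (("B1", "C1"), 0.5), "DM": (("B1", "Cs1"), 0.5)},
        ),
        # M02: SpD = early SpB x SpC cross; SpC* = later SpB x SpC hybrid
        _graph(
            "M02",
            [("DM", "SpD"), ("CsM", "SpC*")],
            {"DM": (("B1", "C1"), 0.5), "CsM": (("B2", "C2"), 0.5)},
            backbone=_BACKBONE_DEEP,
        ),
        # M14: SpC* hybrid of SpB x SpC; SpD = SpC x SpC* cross
        _graph(
            "M14",
            [("CsM", "Cs1"), ("Cs1", "SpC*"), ("DM", "SpD")],
            {"CsM": (("B1", "C1"), 0.5), "DM": (("C1", "Cs1"), 0.5)},
        ),
        # M15: SpC* and SpD independent SpB x SpC hybrids from the same epoch
        _graph(
            "M15",
            [("CsM", "Cs1"), ("Cs1", "SpC*"), ("DM", "SpD")],
            {"CsM": (("B1", "C1"), 0.5), "DM": (("B1", "C1"), 0.5)},
        ),
        # --- one admixture event ------------------------------------------
        # M03: SpC* hybrid of SpB x SpC; SpD sister to SpB
        _graph(
            "M03",
            [("CsM", "SpC*"), ("B1", "SpD")],
            {"CsM": (("B1", "C1"), 0.5)},
        ),
        # M04: SpC* hybrid of SpB x SpC; SpD sister to SpC*
        _graph(
            "M04",
            [("CsM", "Cs1"), ("Cs1", "SpC*"), ("Cs1", "SpD")],
            {"CsM": (("B1", "C1"), 0.5)},
        ),
        # M05: SpC* hybrid of SpB x SpC; SpD sister to SpC
        _graph(
            "M05",
            [("CsM", "SpC*"), ("C1", "SpD")],
            {"CsM": (("B1", "C1"), 0.5)},
        ),
        # M11: SpD hybrid of SpB x SpC (early stems); SpC* sister to SpC
        _graph(
            "M11",
            [("DM", "SpD"), ("C1", "SpC*")],
            {"DM": (("B1", "C1"), 0.5)},
        ),
        # M12: SpC* sister to SpC; SpD = SpB x SpC* cross
        _graph(
            "M12",
            [("C1", "Cs1"), ("Cs1", "SpC*"), ("DM", "SpD")],
            {"DM": (("B1", "Cs1"), 0.5)},
        ),
        # M13: SpD hybrid of SpB x SpC (late stems); SpC* sister to SpC
        _graph(
            "M13",
            [("DM", "SpD"), ("C1", "SpC*")],
            {"DM": (("B2", "C2"), 0.5)},
            backbone=_BACKBONE_DEEP,
        ),
        # --- no admixture --------------------------------------------------
        # M06: SpC* sister to SpC, SpD sister to SpB
        _graph("M06", [("C1", "SpC*"), ("B1", "SpD")], {}),
        # M07: SpC* and SpD both sister to SpC
        _graph("M07", [("C1", "SpC*"), ("C1", "SpD")], {}),
        # M08: SpC* sister to SpC, SpD sister to SpC*
        _graph("M08", [("C1", "Cs1"), ("Cs1", "SpC*"), ("Cs1", "SpD")], {}),
        # M09: SpC* sister to SpC, SpD basal to the SpB/SpC clade
        _graph("M09", [("C1", "SpC*"), ("BC", "SpD")], {}),
        # M10: SpC* and SpD both sister to SpB
        _graph("M10", [("B1", "SpC*"), ("B1", "SpD")], {}),
    ]
    return sorted(models, key=lambda g: g.model_id)


def m01_graph(
    alpha_cs: float = 0.3,
    alpha_d: float = 0.5,
    deep: float = 0.003,
    stem: float = 0.004,
    cs_drift: float = 0.005,
    outgroup: float = 0.01,
) -> AdmixtureGraph:
    """M01 with concrete drift lengths, used as a generating model.

    ``alpha_cs`` is SpC*'s ancestry share from the SpB stem, ``alpha_d``
    SpD's share from SpB; ``cs_drift`` is the post-hybridization drift SpC*
    accrued before the SpD backcross, which is what makes M01 and M02
    empirically distinguishable.
    """
    edges = {
        ("R", "SpA"): outgroup,
        ("R", "BC"): deep,
        ("BC", "B1"): stem,
        ("B1", "SpB"): stem / 2,
        ("BC", "C1"): stem,
        ("C1", "SpC"): stem / 2,
        ("CsM", "Cs1"): cs_drift,
        ("Cs1", "SpC*"): stem / 2,
        ("DM", "SpD"): stem / 4,
    }
    admixture = {
        "CsM": (("B1", "C1"), alpha_cs),
        "DM": (("B1", "Cs1"), alpha_d),
    }
    return AdmixtureGraph("M01", edges, admixture, dict(_LEAVES))


def save_models(models: list[AdmixtureGraph], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([m.to_dict() for m in models], indent=1) + "\n"
    )


def load_models(path: str | Path | None = None) -> list[AdmixtureGraph]:
    """Load candidate models from JSON (packaged default set if no path)."""
    if path is None:
        text = resources.files("hybridpaint").joinpath("data/models.json").read_text()
    else:
        text = Path(path).read_text()
    return [AdmixtureGraph.from_dict(d) for d in json.loads(text)]
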