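"""Packaged reference fixtures.

The package ships the published instance of the evaluation framework as
versioned, hand-curated encodings:

* ``table3_mdm`` - the four elicited relationship matrices (outcome
  weights, stage x main-factor Likert scores, actual-factor x stage
  matrix, actual-factor influence matrix) plus the factor codes;
* ``table3_global_weights`` - the reported 17-entry global-importance
  column (authoritative for the aggregation checks);
* ``table3_af_mf`` - the reported actual-factor x main-factor score block
  (authoritative for goal-conditional rankings);
* ``table4_malmquist`` - the reported 31-province x 6-pair productivity
  index matrix (authoritative for summary arithmetic).

Each JSON fixture carries ``notes`` documenting cells whose printed source
was typographically ambiguous and how they were resolved.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .mdm import FactorCode, LabeledMatrix, MdmSpec

__all__ = ["FIXTURE_NAMES", "load_fixture", "load_mdm_spec"]

FIXTURE_NAMES = ("table3_mdm", "table3_global_weights", "table3_af_mf", "table4_malmquist")


class FixtureError(KeyError):
    pass


def _read_text(filename: str) -> str:
    return resources.files("pedeval").joinpath("data", filename).read_text(encoding="utf-8")


def _block(obj: dict) -> LabeledMatrix:
    return LabeledMatrix(list(obj["rows"]), list(obj["cols"]), obj["values"])


def load_fixture(name: str):
    """Load one packaged fixture by name.

    Returns an :class:`MdmSpec` for ``table3_mdm``, a dict of weights for
    ``table3_global_weights``, a :class:`LabeledMatrix` for
    ``table3_af_mf``, and a pandas DataFrame (DMU rows, period-pair
    columns) for ``table4_malmquist``.
    """
    if name not in FIXTURE_NAMES:
        raise FixtureError(f"unknown fixture {name!r}; available: {list(FIXTURE_NAMES)}")
    if name == "table3_mdm":
        return load_mdm_spec()
    if name == "table3_global_weights":
        data = json.loads(_read_text("table3_global_weights.json"))
        return {k: float(v) for k, v in data["weights"].items()}
    if name == "table3_af_mf":
        data = json.loads(_read_text("table3_af_mf.json"))
        return _block(data["af_mf"])
    import io

    frame = pd.read_csv(io.StringIO(_read_text("table4_malmquist.csv")), index_col=0)
    return frame


def load_mdm_spec() -> MdmSpec:
    """The packaged MDM instance as a validated :class:`MdmSpec`."""
    data = json.loads(_read_text("table3_mdm.json"))
    factors = [FactorCode(f["id"], f.get("label", "")) for f in data["factors"]]
    return MdmSpec(
        mf_weights={k: float(v) for k, v in data["mf_weights"].items()},
        tf_mf=_block(data["tf_mf"]),
        af_tf=_block(data["af_tf"]),
        af_af=_block(data["af_af"]),
        factors=factors,
    )
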