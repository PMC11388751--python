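"""Published reference tables shipped as fixtures.

``printed_confusion`` holds the integer-rounded fold-average confusion
matrices of the reference study (one row per DR technique x selector x
tuner x classifier x disease pair); ``printed_metrics`` the metric
values printed alongside them.  Because the published matrices are
integer-rounded averages, their printed metrics do not always recompute
exactly from the printed counts — consumers should compare field by
field.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_KEY = ["dr", "selector", "tuner", "classifier", "pair"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("ecgdetect.data").joinpath(name).open() as f:
        return pd.read_csv(f)


def printed_confusion() -> pd.DataFrame:
    """Confusion-matrix fixtures: columns table, dr, selector, tuner,
    classifier, pair, tp, tn, fp, fn."""
    return _load("printed_confusion.csv")


def printed_metrics() -> pd.DataFrame:
    """Printed metric fixtures: columns table, dr, selector, tuner,
    classifier, pair, oa, f1, gdr, mcc, er."""
    return _load("printed_metrics.csv")


def merged_tables() -> pd.DataFrame:
    """Confusion rows joined with their printed metrics (333 rows)."""
    conf = printed_confusion().rename(columns={"table": "conf_table"})
    met = printed_metrics().rename(columns={"table": "met_table"})
    out = conf.merge(met, on=_KEY, validate="one_to_one")
    if len(out) != len(conf):
        raise RuntimeError("fixture tables failed to join one-to-one")
    return out
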