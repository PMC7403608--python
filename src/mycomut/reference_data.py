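"""Reference tallies from the 24-line *S. commune* tube experiment.

The packaged CSV holds the per-group (tube size × founder genotype)
marginal counts of de novo mutations by temporal fate and by effect type,
as reported for the original experiment: 300 mutations in total across
four founders grown in narrow and thick tubes.  Only the margins are
published; :func:`reference_tally_records` expands them into per-mutation
rows whose joint fate/type assignment is arbitrary but whose margins are
exact, which is all the tabulation code consumes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .fates import FATES, TYPE_ORDER

_CSV = "tube_experiment_tally.csv"


def load_reference_tally() -> pd.DataFrame:
    """The marginal counts: tube, founder, kind (fate|type), category, count."""
    with resources.files("mycomut.data").joinpath(_CSV).open() as fh:
        return pd.read_csv(fh)


def reference_tally_records() -> pd.DataFrame:
    """Per-mutation records (founder, tube, fate, effect) matching the margins."""
    margins = load_reference_tally()
    rows = []
    for (tube, founder), grp in margins.groupby(["tube", "founder"]):
        fates, effects = [], []
        by_kind = {k: dict(zip(g["category"], g["count"]))
                   for k, g in grp.groupby("kind")}
        for fate in FATES:
            fates.extend([fate] * int(by_kind["fate"].get(fate, 0)))
        for eff in TYPE_ORDER:
            effects.extend([eff] * int(by_kind["type"].get(eff, 0)))
        if len(fates) != len(effects):
            raise ValueError(
                f"inconsistent margins for group ({tube}, {founder}): "
                f"{len(fates)} fates vs {len(effects)} types"
            )
        rows.extend(
            {"tube": tube, "founder": founder, "fate": f, "effect": e}
            for f, e in zip(fates, effects)
        )
    return pd.DataFrame(rows)
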