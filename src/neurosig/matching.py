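"""Exact age/sex matching of controls to a case group.

For each case (visited in a seeded random order, since the outcome of
greedy exact matching depends on order) the matcher forms the pool of
controls with the same sex and the same integer age that have not yet been
taken, and draws one uniformly at random.  Cases whose pool is empty are
recorded as unmatched rather than approximated: no caliper widening or
nearest-neighbour fallback is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MatchResult:
    matched_control_ids: list = field(default_factory=list)
    unmatched_case_ids: list = field(default_factory=list)
    seed: int = 0
    pairs: list = field(default_factory=list)  # (case_id, control_id)

    @property
    def n_matched(self) -> int:
        return len(self.matched_control_ids)


def match_controls(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    keys: tuple[str, ...] = ("sex", "age"),
    seed: int = 0,
) -> MatchResult:
    """Select a without-replacement control subsample exactly matched on keys.

    Age is matched on integer years.  Exhaustion of a stratum is an
    outcome (the case lands in ``unmatched_case_ids``), not an error.
    """
    for df, name in ((cases, "cases"), (controls, "controls")):
        missing = set(keys) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table is missing key columns: {sorted(missing)}")

    def stratum(df):
        parts = []
        for k in keys:
            col = df[k]
            if k == "age":
                col = np.round(col.astype(float)).astype(int)
            parts.append(col.astype(str))
        out = parts[0]
        for p in parts[1:]:
            out = out + "|" + p
        return out

    case_strata = stratum(cases)
    control_strata = stratum(controls)
    pools: dict[str, list] = {}
    for cid, s in zip(controls.index, control_strata):
        pools.setdefault(s, []).append(cid)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    result = MatchResult(seed=seed)
    for i in order:
        case_id = cases.index[i]
        pool = pools.get(case_strata.iloc[i], [])
        if not pool:
            result.unmatched_case_ids.append(case_id)
            continue
        j = rng.integers(len(pool))
        control_id = pool.pop(j)
        result.matched_control_ids.append(control_id)
        result.pairs.append((case_id, control_id))
    return result
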