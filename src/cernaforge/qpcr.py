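"""Relative quantification of qPCR data by the Livak 2^-ddCt method and
concordance against RNA-seq fold changes.

Per replicate, dCt = Ct(target) - Ct(reference); per group, ddCt =
mean dCt(group) - mean dCt(calibrator); fold = 2^-ddCt.  The calibrator
group's own fold is exactly 1 by construction.  Replicate dCt values
are averaged within group before the ddCt step (the common Livak
usage); a per-replicate mode computes one fold per replicate instead.

Junction-spanning (divergent) primer pairs are circRNA-specific: a
bookkeeping check can require that every circRNA target carries a
``junction_spanning`` flag, but primer design itself is upstream of
this tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgumentError

CT_COLUMNS = ["target_id", "group", "replicate", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class RelExpr:
    target_id: str
    group: str
    ddct: float
    fold: float  # 2^-ddct
    dct_sd: float  # dispersion of dCt across replicates


def _validate_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(ct_table.columns)
    if missing:
        raise InvalidArgumentError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct_table[["ct_target", "ct_reference"]].values).all():
        raise InvalidArgumentError("Ct values must be finite")
    return ct_table


def ddct(
    ct_table: pd.DataFrame, calibrator: str, per_replicate: bool = False
) -> list[RelExpr]:
    """2^-ddCt relative expression for every (target, group).

    ``calibrator`` names the reference sample group; it must be present
    for every target.  With ``per_replicate`` the ddCt of each replicate
    against the calibrator mean is reported separately (groups become
    ``group#rep``).
    """
    df = _validate_ct(ct_table).copy()
    df["dct"] = df["ct_target"] - df["ct_reference"]
    out: list[RelExpr] = []
    for target, sub in df.groupby("target_id", sort=True):
        cal = sub[sub["group"] == calibrator]["dct"]
        if cal.empty:
            raise LookupError(f"calibrator group {calibrator!r} missing for {target}")
        cal_mean = cal.mean()
        for group, grp in sub.groupby("group", sort=True):
            sd = float(grp["dct"].std(ddof=1)) if len(grp) > 1 else 0.0
            if per_replicate:
                for _, row in grp.iterrows():
                    d = float(row["dct"] - cal_mean)
                    out.append(
                        RelExpr(target, f"{group}#{int(row['replicate'])}",
                                d, float(2.0 ** -d), sd)
                    )
            else:
                d = float(grp["dct"].mean() - cal_mean)
                out.append(RelExpr(target, str(group), d, float(2.0 ** -d), sd))
    return out


def relexpr_table(results: Iterable[RelExpr]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.target_id, r.group, r.ddct, r.fold, r.dct_sd) for r in results],
        columns=["target_id", "group", "ddct", "fold", "dct_sd"],
    )


def check_junction_flags(primer_flags: Mapping[str, bool], circ_targets: Iterable[str]) -> list[str]:
    """Return circRNA targets whose primer pair is not flagged
    junction-spanning (back-splice-specific amplification bookkeeping)."""
    return sorted(t for t in circ_targets if not primer_flags.get(t, False))


def concordance(
    qpcr_folds: Mapping[str, float], rnaseq_log2fc: Mapping[str, float]
) -> dict[str, float]:
    """Directional agreement between qPCR and RNA-seq per target.

    Compares log2(fold) from qPCR with the RNA-seq log2 fold change over
    the targets present in both; reports the sign-agreement fraction and
    the Spearman correlation of the two vectors.
    """
    shared = sorted(set(qpcr_folds) & set(rnaseq_log2fc))
    if len(shared) < 3:
        raise InvalidArgumentError("need >= 3 paired targets for concordance")
    q = np.log2(np.array([qpcr_folds[t] for t in shared], float))
    r = np.array([rnaseq_log2fc[t] for t in shared], float)
    sign_agree = float(np.mean(np.sign(q) == np.sign(r)))
    scc = float(stats.spearmanr(q, r).statistic)
    return {"n_targets": len(shared), "sign_agreement": sign_agree, "spearman": scc}
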