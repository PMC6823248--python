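"""Directional pathway activation Z-scores and cross-dataset concordance.

Each pathway is a user-supplied registry of member genes with an expected
activation direction (+1/-1).  Against a DE result, ``N+`` counts pathway
genes whose observed DE direction matches expectation and ``N-`` those that
oppose it; the activation score is ``Z = (N+ - N-) / sqrt(N+ + N-)`` — the
published unweighted form of the commercial pathway-activation score.  The
knowledge-base edge weights of the commercial tool are not reproduced, so
numerical equality with its Z values is not claimed.  A pathway is
significant when ``|Z| >= z_cut`` and its exact membership-overlap p with
the DE list is ``<= p_cut`` (both thresholds inclusive).

Concordance: a pathway suppressed in the treated-mouse contrast
(significant, Z < 0) counts as concordant when elevated (Z > z_cut) in at
least ``min_tissues`` of the human disease-tissue profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ValidationError, harmonize_symbol, harmonize_symbols

logger = logging.getLogger("immunosig")


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway: harmonized gene symbol -> expected direction (+1/-1)."""

    name: str
    directions: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("pathway requires a name")
        if not all(d in (1, -1) for d in self.directions.values()):
            raise ValidationError(
                f"pathway {self.name!r}: expected directions must be +1 or -1"
            )


def activation_z(
    de_directions: Mapping[str, int],
    pathways: Sequence[PathwayDefinition],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Per-pathway activation Z and exact overlap p against a DE call set.

    ``de_directions`` maps significant genes to their observed direction
    (+1/-1).  A pathway with no DE member keeps its row with Z missing so
    dataset-to-dataset row alignment survives for concordance.
    """
    from .enrich import hypergeom_tail

    uni = list(dict.fromkeys(harmonize_symbols(universe)))
    uni_set = set(uni)
    de = {harmonize_symbol(g): int(d) for g, d in de_directions.items()}
    bad = [g for g, d in de.items() if d not in (1, -1)]
    if bad:
        raise ValidationError(f"DE directions must be +1/-1; offenders: {bad[:5]}")
    outside = [g for g in de if g not in uni_set]
    if outside:
        raise ValidationError(
            f"DE genes must lie in the universe; offenders: {outside[:5]}"
        )
    N, n = len(uni_set), len(de)
    rows = []
    for pw in pathways:
        members = {g for g in pw.directions if g in uni_set}
        n_plus = sum(
            1 for g in members if g in de and de[g] == pw.directions[g]
        )
        n_minus = sum(
            1 for g in members if g in de and de[g] == -pw.directions[g]
        )
        total = n_plus + n_minus
        z = (n_plus - n_minus) / math.sqrt(total) if total > 0 else np.nan
        k = len(members & de.keys())
        overlap_p = hypergeom_tail(k, N, len(members), n) if members else 1.0
        rows.append(
            {
                "pathway": pw.name,
                "n_genes": len(pw.directions),
                "n_in_universe": len(members),
                "N_plus": n_plus,
                "N_minus": n_minus,
                "Z": z,
                "overlap_p": overlap_p,
            }
        )
    return pd.DataFrame(rows)


def significant_pathways(
    profile: pd.DataFrame, z_cut: float = 2.0, p_cut: float = 0.05
) -> pd.DataFrame:
    """Rows with |Z| >= z_cut and overlap p <= p_cut (inclusive thresholds).

    Adds a ``direction`` column: 'increased' for Z > 0, 'decreased' for Z < 0.
    """
    if z_cut <= 0:
        raise ValidationError("z_cut must be > 0")
    z = profile["Z"]
    keep = z.notna() & (z.abs() >= z_cut) & (profile["overlap_p"] <= p_cut)
    out = profile[keep].copy()
    out["direction"] = np.where(out["Z"] > 0, "increased", "decreased")
    return out


def concordance(
    mouse_profile: pd.DataFrame,
    human_profiles: Mapping[str, pd.DataFrame],
    z_cut: float = 2.0,
    p_cut: float = 0.05,
    min_tissues: int = 2,
) -> tuple[pd.DataFrame, dict]:
    """Cross-species bookkeeping for pathways suppressed in treated mice.

    For each mouse-significant decreased pathway, count the human profiles
    with Z > z_cut for that pathway (a pathway missing from a profile, or
    with missing Z, is non-concordant in that tissue).  Returns a
    per-pathway frame and a summary dict with ``n_total``, ``n_concordant``
    and ``fraction`` (NaN when no pathway qualifies).
    """
    if not human_profiles:
        raise ValidationError("at least one human profile is required")
    mouse_sig = significant_pathways(mouse_profile, z_cut, p_cut)
    decreased = mouse_sig[mouse_sig["direction"] == "decreased"]
    human_z = {
        name: dict(zip(prof["pathway"], prof["Z"]))
        for name, prof in human_profiles.items()
    }
    m = len(human_profiles)
    rows = []
    for _, row in decreased.iterrows():
        pw = row["pathway"]
        zs = {name: human_z[name].get(pw, np.nan) for name in human_profiles}
        count = sum(1 for z in zs.values() if not pd.isna(z) and z > z_cut)
        rec = {"pathway": pw, "mouse_Z": row["Z"]}
        rec.update({f"Z_{name}": zs[name] for name in human_profiles})
        rec.update(
            n_tissues_concordant=count,
            concordant=bool(count >= min_tissues),
        )
        rows.append(rec)
    per_pathway = pd.DataFrame(rows)
    n_total = len(rows)
    n_conc = int(per_pathway["concordant"].sum()) if n_total else 0
    summary = {
        "n_mouse_decreased": n_total,
        "n_concordant": n_conc,
        "n_tissues": m,
        "min_tissues": min_tissues,
        "fraction": (n_conc / n_total) if n_total else float("nan"),
    }
    return per_pathway, summary
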