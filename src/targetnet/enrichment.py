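"""Target-enrichment statistics over communities and coreness levels.

Community enrichment: with i_D and i_PT the target / pending counts inside
community i, and |D|, |PT| the global counts,

    D(i)  = i_D / |D|,     PT(i) = i_PT / |PT|,     rd(i) = D(i) / PT(i).

rd(i) > 1 (strictly) flags community i as *target-like*: targets are
over-represented relative to the global |D|/|PT| odds.

Coreness enrichment: for each occupied level k, let the *shell shares*
p_k^D = (targets at coreness k)/|D| and p_k^PT = (pending at k)/|PT|
(each summing to 1 over levels), and let DR, PR be the global target /
pending ratios.  The enrichment ratios compare the class proportion inside
the level with its global baseline:

    rc_D(k)  = (targets at k / nodes at k) / DR
    rc_PT(k) = (pending at k / nodes at k) / PR

rc_D(k) > 1 flags the level as target-dominated (the target proportion in
the shell exceeds the global level); algebraically rc_D(k) is also the
shell share p_k^D divided by the level's share of all nodes.  By default
levels are coreness-exactly-k shells; ``cumulative=True`` switches to
k-core membership (coreness ≥ k).
"""

from __future__ import annotations

from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .community import CommunityPartition
from .network_io import LabeledProteome

__all__ = ["community_enrichment", "coreness_enrichment"]


def community_enrichment(
    partition: CommunityPartition | Mapping[Hashable, int],
    labels: LabeledProteome,
) -> pd.DataFrame:
    """Per-community target enrichment rows.

    Returns one row per community with columns ``n_targets`` (i_D),
    ``n_pending`` (i_PT), ``d_share`` (D(i)), ``pt_share`` (PT(i)), ``rd``
    and ``target_like``.  rd is +inf when i_PT = 0 with i_D > 0, 0 when
    i_D = 0 with i_PT > 0, and NaN when the community holds neither class
    (cannot occur when the partition covers the labeled node set).
    """
    assignment = (
        partition.assignment
        if isinstance(partition, CommunityPartition)
        else dict(partition)
    )
    n_d = labels.n_targets
    n_pt = labels.n_pending
    if n_d == 0:
        raise ValueError("community enrichment requires at least one target")
    if n_pt == 0:
        raise ValueError("community enrichment requires at least one pending protein")
    communities = sorted(set(assignment.values()))
    rows = []
    for c in communities:
        members = [v for v, ci in assignment.items() if ci == c]
        i_d = sum(1 for v in members if v in labels.targets)
        i_pt = len(members) - i_d
        d_share = i_d / n_d
        pt_share = i_pt / n_pt
        if i_pt > 0:
            rd = d_share / pt_share
        elif i_d > 0:
            rd = np.inf
        else:
            rd = np.nan
        rows.append(
            {
                "community": c,
                "size": len(members),
                "n_targets": i_d,
                "n_pending": i_pt,
                "d_share": d_share,
                "pt_share": pt_share,
                "rd": rd,
                "target_like": bool(rd > 1),
            }
        )
    return pd.DataFrame(rows).set_index("community")


def coreness_enrichment(
    coreness: Mapping[Hashable, int],
    labels: LabeledProteome,
    cumulative: bool = False,
) -> pd.DataFrame:
    """Per-coreness-level target enrichment rows.

    Returns one row per occupied level with the shell shares ``p_d``/
    ``p_pt`` (each summing to 1 over levels) and the enrichment ratios
    ``rc_d``/``rc_pt`` (within-level class proportion over the global
    DR / PR baseline).  By default levels are coreness-exactly-k shells;
    with ``cumulative=True`` they are k-core memberships (coreness ≥ k),
    in which case the shares no longer sum to 1.  Empty levels are omitted.
    """
    n_d = labels.n_targets
    n_pt = labels.n_pending
    if n_d == 0:
        raise ValueError("coreness enrichment requires at least one target")
    if n_pt == 0:
        raise ValueError("coreness enrichment requires at least one pending protein")
    dr = labels.dr
    pr = labels.pr
    levels = sorted(set(coreness.values()))
    rows = []
    for k in levels:
        if cumulative:
            members = [v for v, c in coreness.items() if c >= k]
        else:
            members = [v for v, c in coreness.items() if c == k]
        if not members:
            continue
        k_d = sum(1 for v in members if v in labels.targets)
        k_pt = len(members) - k_d
        size = len(members)
        rc_d = (k_d / size) / dr
        rc_pt = (k_pt / size) / pr
        rows.append(
            {
                "coreness": k,
                "size": size,
                "n_targets": k_d,
                "n_pending": k_pt,
                "p_d": k_d / n_d,
                "p_pt": k_pt / n_pt,
                "rc_d": rc_d,
                "rc_pt": rc_pt,
                "target_dominated": bool(rc_d > 1),
            }
        )
    return pd.DataFrame(rows).set_index("coreness")
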