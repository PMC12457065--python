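"""Signed directed centrality for cross-lagged networks.

Expected influence (EI) sums signed edge weights, so facilitative and
inhibitory pathways are not conflated the way absolute-value strength
centrality conflates them.  in-EI(j) sums incoming edges (column j of W);
out-EI(i) sums outgoing edges (row i).  Autoregressive self-loops are
excluded by default: centrality here is meant to capture cross-symptom
influence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clpn import CLPNetwork


@dataclass
class CentralityTable:
    nodes: tuple[str, ...]
    in_ei: np.ndarray
    out_ei: np.ndarray
    include_autoregressive: bool
    group: str = "all"
    wave_pair: tuple[int, int] = (1, 2)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "wave_pair": f"{self.wave_pair[0]}->{self.wave_pair[1]}",
                "node": list(self.nodes),
                "in_EI": self.in_ei,
                "out_EI": self.out_ei,
            }
        )

    def standardized_view(self) -> pd.DataFrame:
        """Z-scored centralities within the network (plotting convention);
        raw values remain in the table."""
        def zs(v: np.ndarray) -> np.ndarray:
            s = v.std(ddof=0)
            return (v - v.mean()) / s if s > 0 else np.zeros_like(v)

        out = self.frame()
        out["in_EI"] = zs(self.in_ei)
        out["out_EI"] = zs(self.out_ei)
        return out


def _check_estimation_copy(net: CLPNetwork) -> None:
    if net.display_thresholded:
        raise ValueError("centrality must be computed on the estimation copy, "
                         "not a display-thresholded network")


def in_expected_influence(net: CLPNetwork, include_auto: bool = False) -> np.ndarray:
    """Signed sum of incoming edges per node (column sums of W off-diagonal)."""
    _check_estimation_copy(net)
    W = net.W
    s = W.sum(axis=0)
    return s if include_auto else s - np.diag(W)


def out_expected_influence(net: CLPNetwork, include_auto: bool = False) -> np.ndarray:
    """Signed sum of outgoing edges per node (row sums of W off-diagonal)."""
    _check_estimation_copy(net)
    W = net.W
    s = W.sum(axis=1)
    return s if include_auto else s - np.diag(W)


def centrality_table(net: CLPNetwork, include_auto: bool = False) -> CentralityTable:
    return CentralityTable(
        nodes=net.nodes,
        in_ei=in_expected_influence(net, include_auto),
        out_ei=out_expected_influence(net, include_auto),
        include_autoregressive=include_auto,
        group=net.group,
        wave_pair=net.wave_pair,
    )


def rank_centrality(table: CentralityTable, metric: str) -> list[str]:
    """Nodes in descending order of the signed metric; ties break by the
    canonical node order (the order the table carries)."""
    if metric == "in_EI":
        vals = table.in_ei
    elif metric == "out_EI":
        vals = table.out_ei
    else:
        raise ValueError(f"unknown centrality metric {metric!r}")
    order = sorted(range(len(table.nodes)), key=lambda i: (-vals[i], i))
    return [table.nodes[i] for i in order]
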