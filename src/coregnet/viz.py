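"""Network plots: CAZy genes highlighted, secreted-protein genes marked red."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from coregnet.coexpression import CoexpressionNetwork


def plot_network(net: CoexpressionNetwork, ax=None, layout_seed: int = 0):
    """Spring-layout plot; CAZy nodes yellow, secreted nodes red, others grey."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    g = net.graph
    colors = []
    for _, d in g.nodes(data=True):
        if d.get("secreted", False):
            colors.append("#d62728")
        elif d.get("cazy_family", ""):
            colors.append("#ffdf00")
        else:
            colors.append("#bbbbbb")
    pos = nx.spring_layout(g, seed=layout_seed)
    nx.draw_networkx_edges(g, pos, ax=ax, alpha=0.3, width=0.5)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, node_size=25, linewidths=0)
    ax.set_axis_off()
    return ax
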