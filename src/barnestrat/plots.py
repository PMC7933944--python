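"""Strategy raster plots: animal x trial grids of strategy categories."""

from __future__ import annotations

import pandas as pd

from .strategy import STRATEGIES

STRATEGY_COLORS = {
    "direct": "#1b7837",
    "short_chaining": "#5aae61",
    "long_chaining": "#a6dba0",
    "serial": "#c2a5cf",
    "random": "#9970ab",
    "focal_incorrect": "#762a83",
    "unclassified": "#cccccc",
}


def strategy_raster_frame(labels_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot trial labels into an animal (rows) x trial (columns) grid."""
    return labels_df.pivot(index="animal_id", columns="trial_index", values="strategy")


def plot_strategy_raster(labels_df: pd.DataFrame, path=None):
    """Draw the raster with one colour per strategy; save if ``path`` given."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    grid = strategy_raster_frame(labels_df)
    order = sorted(grid.index, key=lambda a: (labels_df.set_index("animal_id")["group"].get(a, ""), a))
    grid = grid.loc[order]
    codes = grid.apply(lambda col: col.map({s: i for i, s in enumerate(STRATEGIES)}))
    cmap = ListedColormap([STRATEGY_COLORS[s] for s in STRATEGIES])
    fig, ax = plt.subplots(figsize=(0.5 * grid.shape[1] + 2, 0.3 * grid.shape[0] + 1.5))
    ax.imshow(codes.to_numpy(dtype=float), cmap=cmap, vmin=-0.5,
              vmax=len(STRATEGIES) - 0.5, aspect="auto", interpolation="nearest")
    ax.set_xticks(range(grid.shape[1]), grid.columns)
    ax.set_yticks(range(grid.shape[0]), grid.index)
    ax.set_xlabel("training trial")
    ax.legend(handles=[Patch(color=STRATEGY_COLORS[s], label=s) for s in STRATEGIES],
              bbox_to_anchor=(1.02, 1), loc="upper left", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
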