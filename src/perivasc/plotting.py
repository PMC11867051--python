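"""Profile plots: evoked z-score vs. distance with the vessel overlay."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .quant import RadialProfile


def plot_profile(profile: RadialProfile, path=None, title: str | None = None):
    """Plot the z-score radial profile; the vessel channel is drawn at its
    display normalisation (maximum rendered at z = 5)."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile.positions_um, profile.z, color="tab:blue", label="sheath z-score")
    if profile.vessel_display is not None:
        ax.plot(
            profile.positions_um,
            profile.vessel_display,
            color="tab:red",
            label="vessel (display, max = 5)",
        )
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("distance from vessel center (µm)")
    ax.set_ylabel("z-score")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return path
    return fig
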