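"""Optional diagnostic plots: damage profiles, flank composition, lengths.

Requires matplotlib (installed with the ``plot`` extra); import is
deferred so the core pipeline has no plotting dependency.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .damage import BASES, DamageProfile, FlankComposition, LengthStats


def _axes(n):
    import matplotlib.pyplot as plt

    return plt.subplots(1, n, figsize=(4.5 * n, 3.2))


def plot_damage_profile(profile: DamageProfile, path: Optional[str] = None):
    """Per-position substitution frequencies from both fragment ends;
    C->T highlighted, all other classes in grey."""
    fig, (ax5, ax3) = _axes(2)
    pos = range(1, profile.window + 1)
    for ax, end, label in ((ax5, 0, "5' end"), (ax3, 1, "3' end")):
        for x in BASES:
            for y in BASES:
                if x == y:
                    continue
                f = [profile.frequency(end, i, x, y) for i in range(profile.window)]
                if x == "C" and y == "T":
                    ax.plot(pos, f, color="crimson", lw=2, label="C>T")
                else:
                    ax.plot(pos, f, color="0.7", lw=0.8)
        ax.set_xlabel(f"position from {label}")
        ax.set_ylabel("substitution frequency")
        ax.set_ylim(bottom=0)
        ax.legend(frameon=False)
    if end == 1:
        ax3.invert_xaxis()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_flank_composition(comp: FlankComposition, path: Optional[str] = None):
    """Reference base composition around fragment termini (read
    orientation); the purine excess just outside the ends is the
    depurination signature."""
    fig, (ax5, ax3) = _axes(2)
    for ax, end, title in ((ax5, "5p", "around 5' ends"), (ax3, "3p", "around 3' ends")):
        df = comp.frequencies(end)
        for base in BASES:
            ax.plot(df["offset"], df[base], marker=".", label=base)
        ax.axvline(0, color="0.8", ls="--", lw=0.8)
        ax.set_xlabel(f"offset {title}")
        ax.set_ylabel("reference base frequency")
        ax.legend(frameon=False, ncol=2)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig


def plot_length_distribution(stats: LengthStats, path: Optional[str] = None):
    """Fragment length histogram with the mean marked."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    lengths = sorted(stats.histogram)
    ax.bar(lengths, [stats.histogram[l] for l in lengths], width=1.0,
           color="steelblue")
    if stats.mean is not None:
        ax.axvline(stats.mean, color="crimson", ls="--",
                   label=f"mean = {stats.mean:.1f} bp")
        ax.legend(frameon=False)
    ax.set_xlabel("fragment length (bp)")
    ax.set_ylabel("fragments")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
    return fig
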