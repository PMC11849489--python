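"""Minimal plotting helpers (optional; all results are also written as TSV)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .features import DiversityProfile, PositionWeightMatrix

# Rough physicochemical colour groups for the 20 standard residues.
_COLORS = {
    **{a: "#2c7fb8" for a in "RKH"},      # basic
    **{a: "#d7301f" for a in "DE"},       # acidic
    **{a: "#31a354" for a in "STNQCGP"},  # polar/small
    **{a: "#636363" for a in "AVLIMFWY"}, # hydrophobic
}


def render_logo(pwm: PositionWeightMatrix, path: str | Path, title: str = "") -> None:
    """Render a PWM as a stacked probability logo (letters scaled by share)."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * pwm.length), 2.5))
    for pos in range(pwm.length):
        row = pwm.probs.iloc[pos]
        bottom = 0.0
        for aa, p in sorted(row.items(), key=lambda kv: kv[1]):
            if p <= 1e-9:
                continue
            ax.text(
                pos + 0.5,
                bottom + p / 2,
                aa,
                ha="center",
                va="center",
                fontsize=6 + 14 * p,
                color=_COLORS.get(aa, "black"),
                family="monospace",
            )
            bottom += p
    ax.set_xlim(0, pwm.length)
    ax.set_ylim(0, 1)
    ax.set_xticks([i + 0.5 for i in range(pwm.length)])
    ax.set_xticklabels(range(1, pwm.length + 1), fontsize=7)
    ax.set_ylabel("probability")
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_diversity(profile: DiversityProfile, path: str | Path) -> None:
    """Renyi curve with the infinite order drawn at the grid edge."""
    alphas = [a if a != float("inf") else max(2 * a2 for a2 in profile.alphas[:-1]) for a in profile.alphas]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(alphas, profile.entropies, marker="o")
    ax.set_xscale("symlog")
    ax.set_xlabel("alpha")
    ax.set_ylabel(f"Renyi entropy (log base {profile.base:g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
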