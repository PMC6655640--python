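"""Matplotlib renderings of identity matrices, coverage and composition."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .core_seq import CompositionProfile  # noqa: E402
from .genome_features import CoverageTrack  # noqa: E402
from .taxonomy import IdentityMatrix  # noqa: E402


def plot_identity_heatmap(matrix: IdentityMatrix, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(matrix.labels),) * 2)
    im = ax.imshow(matrix.values, vmin=0, vmax=100, cmap="Blues")
    ax.set_xticks(range(len(matrix.labels)), matrix.labels,
                  rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.labels)), matrix.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="% identity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_coverage(track: CoverageTrack, path: str | Path,
                  title: str = "") -> None:
    """Density-style strip of 0-1 normalized per-base read counts."""
    fig, ax = plt.subplots(figsize=(8, 1.6))
    ax.imshow(track.normalized[np.newaxis, :], aspect="auto",
              cmap="viridis", vmin=0, vmax=1)
    ax.set_yticks([])
    ax.set_xlabel("genome position (nt)")
    label = f"{track.total_reads} reads, {track.mean_coverage:.0f}x mean"
    ax.set_title(f"{title} {label}".strip(), fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_composition(profile: CompositionProfile, path: str | Path,
                     label: str = "A/G/P fraction") -> None:
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(range(1, profile.n_bins + 1), profile.bin_fractions, "o-")
    ax.set_xlabel("protein bin (N- to C-terminus)")
    ax.set_ylabel(label)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
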