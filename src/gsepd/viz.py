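"""Display artifacts: heatmap of alpha scores (HMA), per-term gene
scatterplot pages with projection overlays, sample PCA, and the DE-gene
heatmap.

Every figure writes a numeric sidecar TSV holding exactly the plotted data,
so results stay testable without pixel comparison.  File names follow the
formulaic convention GSEPD.<groupA>x<nA>.<groupB>x<nB>.GO<digits>.<ext> for
per-term figures, which parses back to the contrast and term unambiguously.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .model import Config, Contrast, GeneSetCollection, SampleTable
from .projection import compute_centroids

logger = logging.getLogger("gsepd")

GROUP_A_COLOR = "#2ca02c"  # green, as for the first contrast group
GROUP_B_COLOR = "#d62728"  # red, second group
NONTESTED_COLOR = "#000000"

_NAME_RE = re.compile(r"^GSEPD\.(?P<ga>.+)x(?P<na>\d+)\.(?P<gb>.+)x(?P<nb>\d+)\.GO(?P<digits>\d+)\.(?P<ext>\w+)$")


def term_figure_name(contrast: Contrast, n_a: int, n_b: int, term_id: str, ext: str) -> str:
    digits = "".join(ch for ch in term_id if ch.isdigit())
    if not digits:
        digits = str(abs(hash(term_id)) % 10**7).zfill(7)
    return f"GSEPD.{contrast.group_a}x{n_a}.{contrast.group_b}x{n_b}.GO{digits}.{ext}"


def parse_term_figure_name(name: str) -> dict:
    """Invert the formulaic file name back to contrast labels, group sizes
    and GO digits."""
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a GSEPD term-figure name: {name!r}")
    d = m.groupdict()
    return {
        "group_a": d["ga"],
        "n_a": int(d["na"]),
        "group_b": d["gb"],
        "n_b": int(d["nb"]),
        "go_digits": d["digits"],
        "ext": d["ext"],
    }


def _sample_color(sid: str, samples: SampleTable, contrast: Contrast) -> str:
    cond = samples.condition_of(sid)
    if cond == contrast.group_a:
        return GROUP_A_COLOR
    if cond == contrast.group_b:
        return GROUP_B_COLOR
    return NONTESTED_COLOR


def _ordered_samples(samples: SampleTable, contrast: Contrast, all_ids: list[str]) -> list[str]:
    a = [s for s in all_ids if samples.condition_of(s) == contrast.group_a]
    b = [s for s in all_ids if samples.condition_of(s) == contrast.group_b]
    rest = [s for s in all_ids if s not in set(a) | set(b)]
    return a + b + rest


def render_hma(
    scores: pd.DataFrame,
    validity: pd.DataFrame,
    samples: SampleTable,
    contrast: Contrast,
    config: Config,
    out_dir: str | Path,
) -> Path | None:
    """Heatmap of alpha scores: qualifying terms (rows, ordered by empirical
    p then term ID) x all samples (columns, tested groups first).  Writes
    HMA.<ext> and the numeric matrix HMA_matrix.tsv; with zero qualifying
    terms writes a note file instead and returns None."""
    out_dir = Path(out_dir)
    qualifying = validity.loc[validity["segregates"]].sort_values(
        ["p_empirical", "term_id"]
    )
    if config.top_n_hma is not None:
        qualifying = qualifying.head(config.top_n_hma)
    if qualifying.empty:
        note = out_dir / "HMA_note.txt"
        note.write_text("no gene set segregated the samples; HMA not drawn\n")
        logger.warning("HMA: no qualifying terms")
        return None

    sample_order = _ordered_samples(samples, contrast, list(scores["sample_id"].unique()))
    mat = scores.pivot(index="term_id", columns="sample_id", values="alpha")
    mat = mat.loc[qualifying["term_id"], sample_order]
    names = dict(zip(validity["term_id"], validity["term_name"]))
    row_labels = [f"{tid} {names.get(tid, '')}".strip() for tid in mat.index]

    sidecar = mat.copy()
    sidecar.index = row_labels
    sidecar.to_csv(out_dir / "HMA_matrix.tsv", sep="\t", index_label="term")

    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(max(6, 0.6 * len(sample_order)), 1.0 + 0.5 * len(mat)),
        gridspec_kw={"height_ratios": [1, 10 * max(1, len(mat))]},
    )
    colors = [_sample_color(s, samples, contrast) for s in sample_order]
    ax_bar.imshow([[i for i in range(len(colors))]], aspect="auto", cmap=matplotlib.colors.ListedColormap(colors))
    ax_bar.set_xticks([])
    ax_bar.set_yticks([])
    vmin, vmax = (0.0, 1.0) if config.normalize_alpha else (None, None)
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="PiYG_r", vmin=vmin, vmax=vmax)
    ax.set_xticks(range(len(sample_order)))
    ax.set_xticklabels([samples.short_label_of(s) for s in sample_order], rotation=90)
    ax.set_yticks(range(len(mat)))
    ax.set_yticklabels(row_labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="alpha")
    fig.tight_layout()
    out = out_dir / f"HMA.{config.figure_format}"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def _gene_pairs(genes: list[str]) -> list[tuple[str, str]]:
    """Consecutive non-overlapping pairs; an odd trailing gene is paired with
    the first gene."""
    pairs = [(genes[i], genes[i + 1]) for i in range(0, len(genes) - 1, 2)]
    if len(genes) % 2 == 1:
        pairs.append((genes[-1], genes[0]))
    return pairs


def render_term_scatterpages(
    term_id: str,
    norm: pd.DataFrame,
    scores: pd.DataFrame,
    collection: GeneSetCollection,
    samples: SampleTable,
    contrast: Contrast,
    config: Config,
    out_dir: str | Path,
) -> Path:
    """Multi-panel scatterplots of a term's genes, two genes per panel, with
    group centroids, the centroid axis, and each sample's projection foot.

    The sidecar TSV holds per-sample panel coordinates and foot coordinates.
    """
    out_dir = Path(out_dir)
    genes = sorted(collection[term_id].members & set(norm.index))
    if len(genes) < 2:
        raise ValueError(f"term {term_id} needs >= 2 genes for scatter pages")
    cent = compute_centroids(norm, genes, samples, contrast)
    gindex = {g: i for i, g in enumerate(genes)}
    a_ids = samples.samples_in(contrast.group_a)
    b_ids = samples.samples_in(contrast.group_b)
    name = term_figure_name(contrast, len(a_ids), len(b_ids), term_id, config.figure_format)
    out = out_dir / name

    tscores = scores.loc[scores["term_id"] == term_id].set_index("sample_id")
    d = cent.axis_norm
    # N-dimensional projection foot of every sample
    feet = {}
    for sid in norm.columns:
        if d > 0:
            feet[sid] = cent.centroid_a + (tscores.loc[sid, "alpha_raw"] / d) * cent.axis
        else:
            feet[sid] = cent.centroid_a.copy()

    pairs = _gene_pairs(genes)
    sidecar_rows = []

    def draw_panel(ax, gx, gy):
        ix, iy = gindex[gx], gindex[gy]
        for sid in norm.columns:
            x, y = norm.at[gx, sid], norm.at[gy, sid]
            fx, fy = feet[sid][ix], feet[sid][iy]
            color = _sample_color(sid, samples, contrast)
            ax.plot([x, fx], [y, fy], color=color, lw=0.8, alpha=0.6)
            ax.scatter([x], [y], marker="^", color=color, s=30)
            ax.scatter([fx], [fy], marker="o", color=color, s=18)
            ax.annotate(samples.short_label_of(sid), (x, y), fontsize=6)
            sidecar_rows.append(
                {"panel": f"{gx}|{gy}", "sample_id": sid, "x": x, "y": y, "foot_x": fx, "foot_y": fy}
            )
        ax.plot(
            [cent.centroid_a[ix], cent.centroid_b[ix]],
            [cent.centroid_a[iy], cent.centroid_b[iy]],
            color="black", lw=2,
        )
        ax.annotate(f"{contrast.group_a}x{len(a_ids)}", (cent.centroid_a[ix], cent.centroid_a[iy]),
                    fontsize=8, weight="bold", color=GROUP_A_COLOR)
        ax.annotate(f"{contrast.group_b}x{len(b_ids)}", (cent.centroid_b[ix], cent.centroid_b[iy]),
                    fontsize=8, weight="bold", color=GROUP_B_COLOR)
        ax.set_xlabel(f"{gx} (log2 normalized)")
        ax.set_ylabel(f"{gy} (log2 normalized)")

    if config.figure_format == "pdf":
        with PdfPages(out) as pdf:
            for gx, gy in pairs:
                fig, ax = plt.subplots(figsize=(5, 5))
                draw_panel(ax, gx, gy)
                fig.suptitle(f"{term_id} {collection[term_id].term_name}", fontsize=9)
                fig.tight_layout()
                pdf.savefig(fig)
                plt.close(fig)
    else:
        ncol = min(3, len(pairs))
        nrow = int(np.ceil(len(pairs) / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(4.5 * ncol, 4.5 * nrow), squeeze=False)
        for ax in axes.ravel()[len(pairs):]:
            ax.axis("off")
        for (gx, gy), ax in zip(pairs, axes.ravel()):
            draw_panel(ax, gx, gy)
        fig.suptitle(f"{term_id} {collection[term_id].term_name}", fontsize=10)
        fig.tight_layout()
        fig.savefig(out, dpi=120)
        plt.close(fig)

    pd.DataFrame(sidecar_rows).to_csv(out.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6g")
    return out


def render_pca(
    norm: pd.DataFrame,
    samples: SampleTable,
    contrast: Contrast,
    config: Config,
    out_dir: str | Path,
) -> Path | None:
    """PCA of samples on the log2-normalized matrix (genes centered); first
    two components plotted and written to PCA_coords.tsv."""
    out_dir = Path(out_dir)
    if norm.shape[1] < 3:
        logger.warning("PCA skipped: fewer than 3 samples")
        return None
    X = norm.to_numpy().T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0.0):
        logger.warning("PCA skipped: zero variance across samples")
        return None
    from sklearn.decomposition import PCA

    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(X)
    tab = pd.DataFrame(
        {"sample_id": norm.columns, "PC1": coords[:, 0], "PC2": coords[:, 1]}
    )
    tab.to_csv(out_dir / "PCA_coords.tsv", sep="\t", index=False, float_format="%.6g")

    fig, ax = plt.subplots(figsize=(6, 5))
    for sid, x, y in zip(norm.columns, coords[:, 0], coords[:, 1]):
        color = _sample_color(sid, samples, contrast)
        ax.scatter([x], [y], color=color)
        ax.annotate(samples.short_label_of(sid), (x, y), fontsize=7)
    var = pca.explained_variance_ratio_ * 100
    ax.set_xlabel(f"PC1 ({var[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({var[1]:.1f}%)")
    fig.tight_layout()
    out = out_dir / f"PCA.{config.figure_format}"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out


def render_de_heatmap(
    norm: pd.DataFrame,
    de: pd.DataFrame,
    calls: dict[str, list[str]],
    samples: SampleTable,
    contrast: Contrast,
    config: Config,
    out_dir: str | Path,
) -> Path | None:
    """Row-scaled expression heatmap of DE genes across all samples, genes
    ordered by p-value.  Constant rows scale to 0."""
    out_dir = Path(out_dir)
    de_genes = de.loc[de["gene_id"].isin(set(calls["all"]))].sort_values(
        ["pvalue", "gene_id"]
    )["gene_id"].tolist()
    if not de_genes:
        (out_dir / "DE_heatmap_note.txt").write_text("no DE genes; heatmap not drawn\n")
        logger.warning("DE heatmap skipped: no DE genes")
        return None
    sample_order = _ordered_samples(samples, contrast, list(norm.columns))
    sub = norm.loc[de_genes, sample_order]
    arr = sub.to_numpy()
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    scaled = np.where(sd > 0, (arr - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    mat = pd.DataFrame(scaled, index=de_genes, columns=sample_order)
    mat.to_csv(out_dir / "DE_heatmap_matrix.tsv", sep="\t", index_label="gene_id", float_format="%.6g")

    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(sample_order)), max(3, 0.15 * len(de_genes))))
    im = ax.imshow(scaled, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(sample_order)))
    ax.set_xticklabels([samples.short_label_of(s) for s in sample_order], rotation=90, fontsize=7)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="row z-score")
    fig.tight_layout()
    out = out_dir / f"DE_heatmap.{config.figure_format}"
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return out
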