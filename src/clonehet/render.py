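"""UpSet-style rendering of combination tables.

A text rendering (dot-matrix membership plus count bars) is always
available and byte-stable; a graphical rendering is produced when
matplotlib is importable.
"""

from __future__ import annotations

from .intersections import CombinationTable

__all__ = ["render_upset_text", "plot_upset"]


def render_upset_text(table: CombinationTable, max_rows: int = 40, bar_width: int = 30) -> str:
    """Plain-text UpSet: one row per sample combination.

    Membership is a dot matrix over the sample columns; the bar is the
    locus count scaled to ``bar_width`` characters.
    """
    rows = table.rows[:max_rows]
    if not rows:
        return f"# no loci carry class {table.cls}\n"
    samples = list(table.sample_names)
    width = max(len(s) for s in samples)
    lines = [f"# class {table.cls}: {table.total_class_loci} loci, showing "
             f"{len(rows)}/{len(table.rows)} combinations"]
    for i in range(width):
        lines.append("  " + " ".join(s.ljust(width)[i] for s in samples))
    max_count = max(r.count for r in rows)
    for r in rows:
        members = set(r.samples)
        dots = " ".join("#" if s in members else "." for s in samples)
        bar = "=" * max(1, round(bar_width * r.count / max_count))
        lines.append(f"  {dots}  {r.count:>8d} {bar}")
    return "\n".join(lines) + "\n"


def plot_upset(table: CombinationTable, path, max_rows: int = 30) -> None:
    """Graphical UpSet plot (bars over a membership dot matrix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = table.rows[:max_rows]
    samples = list(table.sample_names)
    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(6, 0.35 * len(rows) + 2), 2 + 0.3 * len(samples) + 3),
        sharex=True, gridspec_kw={"height_ratios": [3, 1 + 0.2 * len(samples)]},
    )
    xs = range(len(rows))
    ax_bar.bar(xs, [r.count for r in rows], color="#444444")
    ax_bar.set_ylabel(f"{table.cls} loci")
    for x, r in enumerate(rows):
        for y, s in enumerate(samples):
            filled = s in r.samples
            ax_dot.plot(x, y, "o", color="#222222" if filled else "#dddddd", markersize=5)
        member_ys = [samples.index(s) for s in r.samples]
        if len(member_ys) > 1:
            ax_dot.plot([x, x], [min(member_ys), max(member_ys)], color="#222222", lw=1.5)
    ax_dot.set_yticks(range(len(samples)))
    ax_dot.set_yticklabels(samples, fontsize=8)
    ax_dot.set_xticks([])
    ax_dot.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
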