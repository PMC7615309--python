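"""Static figure helpers for sweep results (matplotlib, imported lazily)."""

from __future__ import annotations

from pathlib import Path

from .experiments import SweepResult, aggregate_over

__all__ = ["plot_sweep_pi0", "plot_effects_boxes"]


def plot_sweep_pi0(result: SweepResult, path: str | Path) -> Path:
    """Bias and SE of the MI and CRA estimators against the missing proportion.

    Two panels: (a) simulated MI bias with the exact selected-population bias
    curve and the maximum-bias bound; (b) empirical SEs with the analytic
    endpoint overlays (horizontal lines at the no-missingness and all-missing
    limits).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table.sort_values("pi0")
    fig, (ax_bias, ax_se) = plt.subplots(1, 2, figsize=(10, 4))

    ax_bias.plot(t["pi0"], t["mi_bias"], "o-", label="simulated MI bias")
    if "alpha_obs_bias_analytic" in t:
        ax_bias.plot(t["pi0"], t["alpha_obs_bias_analytic"], "--", label="exact bias curve")
    ax_bias.axhline(t["max_bias_analytic"].iloc[0], color="grey", lw=0.8, label="maximum bias")
    ax_bias.axhline(0.0, color="grey", lw=0.8)
    ax_bias.set_xlabel("proportion of missing outcome values")
    ax_bias.set_ylabel("bias of the exposure coefficient")
    ax_bias.legend(fontsize=8)

    ax_se.plot(t["pi0"], t["mi_se_empirical"], "o-", label="MI (with collider)")
    ax_se.plot(t["pi0"], t["cra_se_empirical"], "s-", label="complete records")
    for col, style in (
        ("se_mi_at_0_analytic", "-"),
        ("se_mi_limit_analytic", "-"),
        ("se_cra_at_0_analytic", "--"),
        ("se_cra_limit_analytic", "--"),
    ):
        ax_se.axhline(t[col].iloc[0], color="grey", lw=0.8, ls=style)
    ax_se.set_xlabel("proportion of missing outcome values")
    ax_se.set_ylabel("SE of the exposure coefficient")
    ax_se.legend(fontsize=8)

    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_effects_boxes(
    result: SweepResult,
    focal: list[str],
    value: str = "max_bias_analytic",
    path: str | Path = "effects.png",
) -> Path:
    """Box-plot grid of bias against the focal effect sizes, marginalizing the
    coefficients that involve the unmeasured confounder."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = aggregate_over(result, focal=focal, value=value)
    panel_col = focal[0]
    panels = sorted(agg[panel_col].unique())
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.4), sharey=True)
    if len(panels) == 1:
        axes = [axes]
    for ax, level in zip(axes, panels):
        sub = agg[agg[panel_col] == level]
        labels = [", ".join(f"{v:g}" for v in row) for row in sub[focal[1:]].to_numpy()]
        boxes = [
            {
                "med": r["median"],
                "q1": r["q1"],
                "q3": r["q3"],
                "whislo": r["lo"],
                "whishi": r["hi"],
                "label": lab,
            }
            for (_, r), lab in zip(sub.iterrows(), labels)
        ]
        ax.bxp(boxes, showfliers=False)
        ax.set_title(f"{panel_col} = {level:g}", fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=7)
    axes[0].set_ylabel(value)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
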