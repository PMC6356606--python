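"""Human-readable rendering of a DiagnosticReport."""

from __future__ import annotations

from . import __version__
from .diagnostics import DiagnosticReport


def render_text(report: DiagnosticReport) -> str:
    """Plain-text summary, ordered correlations -> AUROC -> cutoff -> prevalence."""
    c = report.correlations
    co = report.cutoff
    pv = report.prevalence.as_dict()
    lines = [
        f"plcscore v{__version__} — diagnostic report (n={report.n})",
        "",
        "Spearman correlation with histology (rho [95% CI], p):",
    ]
    for key, label in (
        ("overall", "Overall Score   "),
        ("partial_b", "Partial Score B "),
        ("partial_c", "Partial Score C "),
    ):
        r = c[key]
        lines.append(
            f"  {label} {r.rho:+.4f} [{r.ci_low:+.3f}, {r.ci_high:+.3f}], p={r.p_value:.4f}"
        )
    lines += [
        "",
        f"AUROC (Partial Score C): {report.roc.auroc:.3f} "
        f"[{report.roc.auroc_ci_low:.3f}, {report.roc.auroc_ci_high:.3f}] "
        f"({report.roc.ci_method})",
        "",
        f"Youden-optimal cutoff: score >= {co.cutoff:g}",
        f"  sensitivity {100*co.sensitivity:.0f}%  specificity {100*co.specificity:.0f}%"
        f"  J={co.youden_j:.3f}",
        f"  confusion: TP={co.tp} FP={co.fp} TN={co.tn} FN={co.fn}",
        "",
        "Pattern prevalence:",
        f"  histology positive : {pv['n_histology_pos']}/{pv['n']} ({pv['histology_pos_pct']}%)",
        f"  all Pattern A      : {pv['n_all_pattern_a']} ({pv['all_pattern_a_pct']}%)",
        f"  Pattern B only     : {pv['n_b_only']} ({pv['b_only_pct']}%)",
        f"  any Pattern C      : {pv['n_any_c']} ({pv['any_c_pct']}%)"
        f" — {pv['n_true_pos']} true / {pv['n_false_pos']} false positives",
        "",
        f"Options: {report.options}",
    ]
    return "\n".join(lines) + "\n"
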