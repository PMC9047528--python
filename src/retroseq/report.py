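"""Deterministic markdown rendering of an evaluation report.

Percentages are printed with one decimal, matching the conventional table
style for this benchmark family; full precision stays in the JSON.
"""

from __future__ import annotations


class ReportRenderError(KeyError):
    pass


def _pct(x: float) -> str:
    return f"{100 * x:.1f}%"


def render_report(report: dict) -> str:
    """Render the evaluation report dict (EvalReport.to_dict) as markdown."""
    for section in ("n_test", "top_n", "per_class_top_n", "invalidity_rate"):
        if section not in report:
            raise ReportRenderError(f"missing report section {section!r}")
    lines: list[str] = []
    lines.append("# Evaluation report")
    lines.append("")
    lines.append(f"Test records: {report['n_test']}")
    lines.append("")

    lines.append("## Top-N exact-match accuracy")
    lines.append("")
    lines.append("| N | accuracy |")
    lines.append("|---|----------|")
    for n, acc in sorted(report["top_n"].items(), key=lambda kv: int(kv[0])):
        lines.append(f"| top-{n} | {_pct(acc)} |")
    lines.append("")

    lines.append("## Per-class accuracy")
    lines.append("")
    per_class = report["per_class_top_n"]
    if per_class:
        ns = sorted({int(n) for d in per_class.values() for n in d}, key=int)
        lines.append("| class | " + " | ".join(f"top-{n}" for n in ns) + " |")
        lines.append("|---" * (len(ns) + 1) + "|")
        for cid in sorted(per_class, key=int):
            row = per_class[cid]
            cells = " | ".join(_pct(row[str(n)] if str(n) in row else row[n]) for n in ns)
            lines.append(f"| {cid} | {cells} |")
    else:
        lines.append("none")
    lines.append("")

    lines.append("## Grammatical invalidity (rank 1)")
    lines.append("")
    lines.append(f"Overall: {_pct(report['invalidity_rate'])}")
    if report.get("per_class_invalidity"):
        lines.append("")
        lines.append("| class | invalidity |")
        lines.append("|---|---|")
        for cid in sorted(report["per_class_invalidity"], key=int):
            lines.append(f"| {cid} | {_pct(report['per_class_invalidity'][cid])} |")
    lines.append("")

    lines.append("## Failure categories")
    lines.append("")
    cats = report.get("failure_categories") or {}
    if cats:
        lines.append("| category | count | rate |")
        lines.append("|---|---|---|")
        for cat, (count, rate) in sorted(cats.items(), key=lambda kv: (kv[0] == "total", kv[0])):
            lines.append(f"| {cat} | {count} | {_pct(rate)} |")
    else:
        lines.append("none")
    lines.append("")

    corrected = report.get("corrected")
    if corrected:
        lines.append('## Corrected ("true") accuracy')
        lines.append("")
        lines.append(f"Exact matches: {corrected['exact_match_count']} "
                     f"({_pct(corrected['exact_fraction'])})")
        lines.append(f"Plausible annotations: {corrected['plausible_count']}")
        lines.append(f"Corrected accuracy: {_pct(corrected['corrected_fraction'])} "
                     f"(rate-sum form {corrected['rate_sum_pct']:.1f}%)")
        lines.append("")
        lines.append("| reaction type | count | rate |")
        lines.append("|---|---|---|")
        for t, row in sorted(corrected["breakdown"].items(),
                             key=lambda kv: (kv[0] == "total", kv[0])):
            lines.append(f"| {t} | {row['count']} | {_pct(row['rate'])} |")
        lines.append("")
    return "\n".join(lines) + "\n"
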