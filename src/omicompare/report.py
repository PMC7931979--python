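"""HTML report assembly.

A report bundles the figures and tables one analysis run produced into a
single HTML index, with the settings snapshot appended so the run can be
replayed from the command line.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field
from pathlib import Path

import jinja2

from .datamodel import ConfigurationError, SettingsSnapshot, ValidationError, _snapshot_to_json

__all__ = ["ReportSection", "ReportBundle", "generate_report"]

_TEMPLATE = jinja2.Template(
    """<!DOCTYPE html>
<html>
<head>
<meta charset="utf-8">
<title>{{ title }}</title>
<style>
 body { font-family: sans-serif; margin: 2em; max-width: 70em; }
 h2 { border-bottom: 1px solid #ccc; padding-top: 1em; }
 img { max-width: 100%; }
 table { border-collapse: collapse; font-size: 0.85em; }
 td, th { border: 1px solid #ccc; padding: 2px 8px; }
 pre { background: #f6f6f6; padding: 1em; overflow-x: auto; }
</style>
</head>
<body>
<h1>{{ title }}</h1>
{% for section in sections %}
<h2>{{ section.title }}</h2>
{% if section.text %}<p>{{ section.text }}</p>{% endif %}
{% for fig in section.figures %}
{% if embed %}<img alt="{{ fig.name }}" src="data:image/png;base64,{{ fig.b64 }}">
{% else %}<img alt="{{ fig.name }}" src="{{ fig.rel }}">{% endif %}
{% endfor %}
{% for tab in section.tables %}
<p><a href="{{ tab.rel }}">{{ tab.name }}</a></p>
{% endfor %}
{% endfor %}
<h2>Settings</h2>
<pre>{{ settings_json }}</pre>
</body>
</html>
"""
)


@dataclass
class ReportSection:
    title: str
    figures: list = field(default_factory=list)  # paths to PNG files
    tables: list = field(default_factory=list)   # paths to TSV files
    text: str = ""


@dataclass
class ReportBundle:
    output_dir: Path
    html_path: Path
    figures: list
    tables: list
    settings: SettingsSnapshot


def generate_report(
    output_dir: str | Path,
    sections: list[ReportSection],
    settings: SettingsSnapshot,
    title: str = "omicompare report",
    embed_figures: bool = True,
) -> ReportBundle:
    """Write ``report.html`` indexing the given sections.

    Every referenced figure/table must exist on disk; an empty section list
    is an error (nothing is written). With ``embed_figures`` PNGs are
    inlined base64 so the HTML is self-contained; otherwise figures are
    relative-linked.
    """
    if not sections:
        raise ConfigurationError("report needs at least one section")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    all_figures, all_tables = [], []
    rendered_sections = []
    for section in sections:
        figs = []
        for f in section.figures:
            f = Path(f)
            if not f.exists():
                raise ValidationError(f"report references missing figure: {f}")
            entry = {"name": f.name, "rel": _rel(f, output_dir)}
            if embed_figures:
                entry["b64"] = base64.b64encode(f.read_bytes()).decode("ascii")
            figs.append(entry)
            all_figures.append(f)
        tabs = []
        for t in section.tables:
            t = Path(t)
            if not t.exists():
                raise ValidationError(f"report references missing table: {t}")
            tabs.append({"name": t.name, "rel": _rel(t, output_dir)})
            all_tables.append(t)
        rendered_sections.append(
            {"title": section.title, "text": section.text, "figures": figs, "tables": tabs}
        )
    html = _TEMPLATE.render(
        title=title,
        sections=rendered_sections,
        settings_json=_snapshot_to_json(settings),
        embed=embed_figures,
    )
    html_path = output_dir / "report.html"
    html_path.write_text(html, encoding="utf-8")
    return ReportBundle(
        output_dir=output_dir,
        html_path=html_path,
        figures=all_figures,
        tables=all_tables,
        settings=settings,
    )


def _rel(path: Path, base: Path) -> str:
    try:
        return str(path.resolve().relative_to(base.resolve()))
    except ValueError:
        return str(path)
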