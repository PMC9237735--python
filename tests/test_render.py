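"""Layout geometry and structural checks on rendered SVG/HTML output."""

import xml.etree.ElementTree as ET

import pytest

from isostack import (
    build_coordinate_map,
    cluster_reads,
    compute_layout,
    default_truth,
    render_interactive,
    render_static,
    simulate_reads,
)
from isostack.altexons import call_alt_exons
from isostack.cluster import order_clusters
from isostack.mismatch import find_mismatches
from isostack.model import GenomicInterval, ParameterError
from isostack.render import FEATURE_COLORS


def build_spec(truth, dataset, with_sites=True, with_annotation=True):
    reads = dataset.reads
    exonic = [e for r in reads for e in r.exons] + truth.gene.exons
    cmap = build_coordinate_map(exonic, truth.gene.span)
    result = cluster_reads(reads)
    ordered = [
        (ct, order_clusters(cs)) for ct, cs in sorted(result.by_cell_type().items())
    ]
    calls = call_alt_exons(reads, truth.gene)
    sites, obs = ([], [])
    if with_sites:
        sites, obs = find_mismatches(
            str(dataset.paths["sam"]), str(dataset.paths["fasta"]), truth.gene.span
        )
    return compute_layout(
        ordered, cmap, alt_calls=calls, sites=sites,
        annotation=truth.gene if with_annotation else None, observations=obs,
    )


@pytest.fixture(scope="module")
def spec(truth, dataset):
    return build_spec(truth, dataset)


class TestComputeLayout:
    def test_one_row_per_retained_read(self, spec, dataset):
        n_read_rows = sum(len(rows) for _, rows in spec.tracks)
        assert n_read_rows == len(dataset.reads)
        assert spec.n_rows == n_read_rows + len(spec.annotation_rows)

    def test_six_cell_types_give_six_sections_plus_annotation(self, tmp_path):
        cts = ["Excit", "Inhib", "Astro", "Oligo", "Micro", "OPC"]
        truth6 = default_truth(seed=2, cell_types=cts)
        ds6 = simulate_reads(truth6, {ct: 15 for ct in cts}, seed=2, outdir=tmp_path)
        spec6 = build_spec(truth6, ds6, with_sites=False)
        assert [ct for ct, _ in spec6.tracks] == sorted(cts)
        assert len(spec6.annotation_rows) == len(truth6.gene.transcripts)

    def test_rows_within_a_cell_type_are_contiguous(self, spec):
        for _, rows in spec.tracks:
            idx = [r.row for r in rows]
            assert idx == list(range(idx[0], idx[0] + len(idx)))

    def test_no_glyph_extends_beyond_axis(self, spec):
        for r in spec.rects:
            assert 0 <= r.x0 <= r.x1 <= spec.axis_length + 1e-6
        for d in spec.dots:
            assert 0 <= d.x <= spec.axis_length + 1e-6

    def test_alternative_exon_boxes_use_the_alternative_color(self, spec):
        roles = {r.role for r in spec.rects}
        assert "alt_exon" in roles
        for r in spec.rects:
            if r.role == "alt_exon":
                assert r.color == FEATURE_COLORS["alt_exon"]

    def test_dots_only_for_passing_sites_on_carrying_rows(self, truth, dataset, spec):
        sites, obs = find_mismatches(
            str(dataset.paths["sam"]), str(dataset.paths["fasta"]), truth.gene.span
        )
        passing = {(s.ref_pos, s.kind) for s in sites if s.passes}
        assert {(d.kind) for d in spec.dots} <= {k for _, k in passing}
        expected_dots = sum(
            1 for o in obs if (o.ref_pos, o.kind) in passing
        )
        assert len(spec.dots) == expected_dots

    def test_zero_passing_sites_means_no_dots(self, truth, dataset):
        spec = build_spec(truth, dataset, with_sites=False)
        assert spec.dots == []

    def test_empty_cluster_list_is_an_error(self, truth, dataset):
        exonic = [e for r in dataset.reads for e in r.exons]
        cmap = build_coordinate_map(exonic, truth.gene.span)
        with pytest.raises(ParameterError, match="[Nn]othing to plot"):
            compute_layout([], cmap)


def _svg_count(path, prefix):
    tree = ET.parse(path)
    return sum(
        1
        for el in tree.iter()
        if el.get("id", "").startswith(prefix)
    )


class TestRenderStatic:
    def test_svg_element_counts_match_spec(self, spec, tmp_path):
        out = tmp_path / "fig.svg"
        render_static(spec, str(out))
        by_role = {"exon": 0, "alt_exon": 0, "annotation": 0}
        for r in spec.rects:
            by_role[r.role] += 1
        assert _svg_count(out, "exon-rect") == by_role["exon"]
        assert _svg_count(out, "alt-rect") == by_role["alt_exon"]
        assert _svg_count(out, "ann-rect") == by_role["annotation"]
        assert _svg_count(out, "mm-dot") == len(spec.dots)

    def test_no_dot_elements_without_mismatches(self, truth, dataset, tmp_path):
        spec = build_spec(truth, dataset, with_sites=False)
        out = tmp_path / "fig.svg"
        render_static(spec, str(out))
        assert _svg_count(out, "mm-dot") == 0

    def test_rendering_twice_gives_identical_element_counts(self, spec, tmp_path):
        a, b = tmp_path / "a.svg", tmp_path / "b.svg"
        render_static(spec, str(a))
        render_static(spec, str(b))
        for prefix in ("exon-rect", "alt-rect", "ann-rect", "mm-dot", "intron-line"):
            assert _svg_count(a, prefix) == _svg_count(b, prefix)

    def test_pdf_and_png_are_written(self, spec, tmp_path):
        for fmt in ("pdf", "png"):
            out = tmp_path / f"fig.{fmt}"
            render_static(spec, str(out), fmt)
            assert out.stat().st_size > 0

    def test_unknown_format_rejected(self, spec, tmp_path):
        with pytest.raises(ParameterError):
            render_static(spec, str(tmp_path / "fig.tiff"), "tiff")


class TestRenderInteractive:
    def test_html_embeds_one_trace_per_cell_type(self, spec, tmp_path):
        out = tmp_path / "fig.html"
        render_interactive(spec, str(out))
        text = out.read_text()
        for ct, _ in spec.tracks:
            assert f'id="trace-{ct}"' in text
        assert text.count('class="trace"') == len(spec.tracks) + 1  # + annotation

    def test_without_annotation_no_annotation_trace(self, truth, dataset, tmp_path):
        spec = build_spec(truth, dataset, with_annotation=False)
        out = tmp_path / "fig.html"
        render_interactive(spec, str(out))
        assert 'id="trace-annotation"' not in out.read_text()

    def test_hover_payloads_carry_read_and_site_details(self, spec, tmp_path):
        out = tmp_path / "fig.html"
        render_interactive(spec, str(out))
        text = out.read_text()
        some_read = spec.tracks[0][1][0]
        assert f"read {some_read.read_id}" in text
        assert f"cluster size {some_read.cluster_size}" in text
        if spec.dots:
            d = spec.dots[0]
            assert f"{d.kind} | frequency {d.freq_pct:.2f}%" in text
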