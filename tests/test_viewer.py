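"""The HTML table viewer index and its filter semantics."""

import random

import pytest

from svblocks.viewer import (
    ViewerIndexRow,
    build_index,
    emit_viewer,
    filter_rows,
    write_index_tsv,
)
from svblocks import formats_io
from svblocks.pipeline import run_plot, run_viewer


def synthetic_index(n=500, seed=13):
    rng = random.Random(seed)
    chrom_pool = [f"chr{i}" for i in range(1, 23)]
    rows = []
    for i in range(n):
        chroms = rng.sample(chrom_pool, rng.choice([1, 1, 1, 2]))
        start = rng.randrange(1_000, 5_000_000)
        size = rng.randrange(500, 200_000)
        nvar = rng.randint(1, 12)
        rows.append(ViewerIndexRow(
            chrom=chroms[0], start=start, end=start + size, region_size=size,
            variant_ids=[f"sv{i}_{k}" for k in range(nvar)], n_variants=nvar,
            sample_id=rng.choice(["HG001", "HG002", "HG003"]),
            image_path=f"img{i}.svg", chroms=chroms,
        ))
    return rows


def brute_force_filter(rows, variant_id=None, sample_id=None, n_variants=None,
                       size=None, chroms=None):
    kept = []
    for r in rows:
        ok = True
        if variant_id is not None:
            ok = ok and variant_id in r.variant_ids
        if sample_id is not None:
            ok = ok and r.sample_id == sample_id
        if n_variants is not None:
            lo, hi = n_variants
            ok = ok and (lo is None or r.n_variants >= lo)
            ok = ok and (hi is None or r.n_variants <= hi)
        if size is not None:
            lo, hi = size
            ok = ok and (lo is None or r.region_size >= lo)
            ok = ok and (hi is None or r.region_size <= hi)
        if chroms is not None:
            ok = ok and any(c in chroms for c in r.chroms)
        if ok:
            kept.append(r)
    return kept


def test_filter_function_matches_bruteforce_scan():
    rows = synthetic_index()
    rng = random.Random(29)
    cases = [
        {},
        {"n_variants": (2, 8), "size": (8_000, 90_000)},  # all chromosomes
        {"chroms": {"chr2"}},
        {"sample_id": "HG002", "size": (None, 50_000)},
        {"variant_id": rows[17].variant_ids[0]},
    ]
    for _ in range(20):
        cases.append({
            "n_variants": (rng.randint(0, 6), rng.randint(6, 14)),
            "size": (rng.randrange(0, 100_000), rng.randrange(100_000, 250_000)),
            "chroms": set(rng.sample([f"chr{i}" for i in range(1, 23)], 3)),
        })
    for case in cases:
        got = filter_rows(rows, **case)
        expected = brute_force_filter(rows, **case)
        assert [r.image_path for r in got] == [r.image_path for r in expected]


def test_range_bounds_inclusive():
    rows = synthetic_index(100)
    exact = rows[0].region_size
    kept = filter_rows(rows, size=(exact, exact))
    assert rows[0] in kept
    assert all(r.region_size == exact for r in kept)


def test_chromosome_filter_keeps_translocations():
    row = ViewerIndexRow(chrom="chr12", start=0, end=10, region_size=10,
                         chroms=["chr12", "chr2"], image_path="x.svg")
    assert filter_rows([row], chroms={"chr2"}) == [row]
    assert filter_rows([row], chroms={"chr3"}) == []


def test_no_filters_shows_all_rows():
    rows = synthetic_index(50)
    assert filter_rows(rows) == rows


@pytest.fixture()
def rendered(suite, tmp_path):
    """Images + merged viewer over two samples processed together."""
    names = ["inv", "balanced-trans-dup"]
    image_dir = tmp_path / "images"
    json_paths = []
    for name in names:
        scenario = suite[name]
        run_plot(scenario.cfg, [scenario.json_path], image_dir=str(image_dir))
        json_paths.append(scenario.json_path)
    docs = [formats_io.read_json(p) for p in json_paths]
    return docs, image_dir, json_paths


def test_build_index_rows_and_sorting(rendered):
    docs, image_dir, _ = rendered
    rows = build_index(docs, image_dir)
    assert len(rows) == 2
    samples = {r.sample_id for r in rows}
    assert samples == {"inv", "balanced-trans-dup"}
    trans = next(r for r in rows if r.sample_id == "balanced-trans-dup")
    assert trans.chroms == ["chr2", "chr12"]
    assert trans.region_size == sum(e - s for s, e in
                                    docs[1].events[0].region.values())
    inv_row = next(r for r in rows if r.sample_id == "inv")
    assert inv_row.region_size == inv_row.end - inv_row.start
    assert inv_row.n_variants == len(inv_row.variant_ids) > 0


def test_missing_image_skips_row_with_warning(rendered, caplog):
    docs, image_dir, _ = rendered
    with caplog.at_level("WARNING"):
        rows = build_index(docs, image_dir, image_ext="png")  # no PNGs rendered
    assert rows == []
    assert any("row skipped" in rec.message for rec in caplog.records)


def test_emit_viewer_single_self_contained_file(rendered, tmp_path):
    docs, image_dir, _ = rendered
    rows = build_index(docs, image_dir)
    out = image_dir / "index.html"
    emit_viewer(rows, out)
    page = out.read_text()
    assert "<html" in page and "rowPasses" in page
    for row in rows:
        assert row.image_path in page
        assert str(image_dir) not in page, "image links must stay relative"
    write_index_tsv(rows, tmp_path / "index.tsv")
    lines = (tmp_path / "index.tsv").read_text().splitlines()
    assert len(lines) == len(rows) + 1


def test_empty_index_still_valid_page(tmp_path):
    out = tmp_path / "empty.html"
    emit_viewer([], out)
    assert "ROWS = []" in out.read_text()


def test_run_viewer_merges_samples(rendered, suite, tmp_path):
    docs, image_dir, json_paths = rendered
    cfg = suite["inv"].cfg
    html = run_viewer(cfg, json_paths, image_dir=str(image_dir))
    rows = open(html).read()
    assert "balanced-trans-dup" in rows and '"sample_id": "inv"' in rows
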