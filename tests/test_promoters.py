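"""Promoter extraction, overlap elimination, MCR masking, background sets."""

import numpy as np
import pandas as pd
import pytest

from regmine.promoters import (
    PROMOTER_LENGTH,
    build_background,
    extract_promoters,
    genomic_to_local,
    mask_regions,
    promoter_interval,
)
from regmine.sequences import GenomicInterval

from conftest import make_set


def _ann(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def _genome(rng, name="chr1", length=6000):
    bases = np.array(list("ACGT"))
    return {name: "".join(bases[rng.integers(0, 4, size=length)])}


def test_promoter_interval_orientation():
    assert promoter_interval(2000, "+") == (1000, 2500)
    assert promoter_interval(2000, "-") == (1500, 3000)


def test_extract_plus_strand(rng):
    genome = _genome(rng)
    ann = _ann([["gA", "chr1", 2000, "+"]])
    seqs, ivs = extract_promoters(ann, genome, ["gA"])
    assert len(seqs["gA"]) == PROMOTER_LENGTH
    assert seqs["gA"].to_string() == genome["chr1"][1000:2500]
    assert ivs["gA"] == GenomicInterval("chr1", 1000, 2500, "+")


def test_extract_minus_strand_reverse_complements(rng):
    genome = _genome(rng)
    ann = _ann([["gB", "chr1", 2000, "-"]])
    seqs, _ = extract_promoters(ann, genome, ["gB"])
    window = genome["chr1"][1500:3000]
    comp = str.maketrans("ACGT", "TGCA")
    assert seqs["gB"].to_string() == window.translate(comp)[::-1]


def test_extract_multi_isoform_uses_5prime_most_tss(rng):
    genome = _genome(rng)
    ann = _ann([["gA", "chr1", 2400, "+"], ["gA", "chr1", 2000, "+"]])
    _, ivs = extract_promoters(ann, genome, ["gA"])
    assert ivs["gA"].start == 1000  # TSS 2000 chosen on plus strand


def test_overlapping_promoters_eliminated(rng):
    genome = _genome(rng)
    ann = _ann([["gA", "chr1", 2000, "+"], ["gB", "chr1", 2100, "+"],
                ["gC", "chr1", 4500, "+"]])
    seqs, _ = extract_promoters(ann, genome, ["gA", "gB", "gC"])
    # lexicographically earlier gene wins the overlap
    assert set(seqs.names) == {"gA", "gC"}


def test_short_promoter_drop_and_pad(rng):
    genome = _genome(rng)
    ann = _ann([["gEdge", "chr1", 500, "+"]])  # window would start at -500
    dropped, _ = extract_promoters(ann, genome, ["gEdge"], short_promoters="drop")
    assert len(dropped) == 0
    padded, _ = extract_promoters(ann, genome, ["gEdge"], short_promoters="pad")
    assert len(padded["gEdge"]) == PROMOTER_LENGTH
    assert int(padded["gEdge"].mask[:500].sum()) == 500  # N-padded side masked


def test_genomic_to_local_minus_strand():
    prom = GenomicInterval("chr1", 1000, 2500, "-")
    mask = GenomicInterval("chr1", 1000, 1010, "+")
    # the genomic left edge maps to the local right edge after RC
    assert genomic_to_local(mask, prom) == (1490, 1500)
    assert genomic_to_local(GenomicInterval("chr2", 1000, 1010), prom) is None


def test_mask_regions_unions_with_existing(rng):
    seqs = make_set(["ACGTACGTac"])
    out = mask_regions(seqs, [], local_masks={"s1": [(0, 2)]})
    assert list(out["s1"].mask) == [True, True] + [False] * 6 + [True, True]
    # original untouched
    assert not seqs["s1"].mask[:2].any()


def test_mask_regions_clips_with_warning():
    seqs = make_set(["ACGTACGT"])
    with pytest.warns(UserWarning, match="clipped"):
        out = mask_regions(seqs, [], local_masks={"s1": [(6, 12)]})
    assert int(out["s1"].mask.sum()) == 2


def test_build_background_excludes_and_matches_count(rng):
    genome = _genome(rng, length=40000)
    rows = [[f"g{i:02d}", "chr1", 1200 + 1600 * i, "+"] for i in range(20)]
    ann = _ann(rows)
    bg, ivs = build_background(ann, genome, {"g00", "g01"}, 5, rng)
    assert len(bg) == 5
    assert not ({"g00", "g01"} & set(bg.names))
    assert set(bg.names) == set(ivs)


def test_build_background_warns_when_short(rng):
    genome = _genome(rng, length=4000)
    ann = _ann([["g1", "chr1", 1200, "+"], ["g2", "chr1", 2500, "+"]])
    with pytest.warns(UserWarning, match="background"):
        bg, _ = build_background(ann, genome, set(), 5, rng)
    assert len(bg) <= 2
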