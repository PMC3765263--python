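"""Target-site rule tests: positional rules, decoy set and a window-scan
brute-force oracle."""

import numpy as np
import pytest

from mircycle.annotate import revcomp
from mircycle.structure import duplex_energy, perfect_complement_energy
from mircycle.synthetic import target_rule_fixture
from mircycle.targets import TargetRules, align_site, check_rules, scan_utrs

MIRNA = "TGAGGTAGTAGGTTGTATAGTT"  # 22 nt


def complement_window(mirna, mismatch_at=(), wobble_at=()):
    """Build a 5'->3' target window complementary to *mirna* except at the
    given 1-based miRNA positions."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    gu = {"G": "T", "T": "G"}
    L = len(mirna)
    w = [comp[b] for b in mirna[::-1]]
    for p in mismatch_at:
        b = mirna[p - 1]
        w[L - p] = next(x for x in "ACGT" if x not in {comp[b], gu.get(b, "")})
    for p in wobble_at:
        w[L - p] = gu[mirna[p - 1]]
    return "".join(w)


class TestAlignSite:
    def test_perfect_complement_all_wc(self):
        cls = align_site(MIRNA, complement_window(MIRNA))
        assert cls == ["WC"] * 22

    def test_single_wobble_scores_half(self):
        cls = align_site(MIRNA, complement_window(MIRNA, wobble_at=[4]))
        assert cls[3] == "GU"
        verdicts, _ = check_rules(cls)
        assert verdicts["max_mismatches"]  # 0.5 <= 4

    def test_mirna_against_itself_mostly_mismatched(self):
        cls = align_site(MIRNA, MIRNA)
        assert cls.count("WC") < 8

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            align_site(MIRNA, "ACGT")


class TestCheckRules:
    def test_mismatch_at_position_10_rejected(self):
        cls = align_site(MIRNA, complement_window(MIRNA, mismatch_at=[10]))
        verdicts, accept = check_rules(cls)
        assert not accept
        assert [r for r, v in verdicts.items() if not v] == ["no_mm_10_11"]

    def test_wobble_at_position_11_also_rejected(self):
        # G:U counts as a mismatch *position* for the positional exclusions
        cls = align_site(MIRNA, complement_window(MIRNA, wobble_at=[11]))
        verdicts, accept = check_rules(cls)
        assert not accept and not verdicts["no_mm_10_11"]

    def test_three_adjacent_mismatches_rejected(self):
        cls = align_site(MIRNA, complement_window(MIRNA, mismatch_at=[14, 15, 16]))
        verdicts, accept = check_rules(cls)
        assert not accept and not verdicts["max_adjacent_mm"]

    def test_spec_worked_accept_case(self):
        """3 full mismatches at 18/20/22 plus one early wobble: total 3.5
        <= 4 and 0.5 in positions 1-12; all positional rules pass."""
        cls = align_site(
            MIRNA, complement_window(MIRNA, mismatch_at=[18, 20, 22], wobble_at=[2])
        )
        verdicts, accept = check_rules(cls, mfe_ratio=None)
        assert accept

    def test_weighted_score_in_seed_region(self):
        # six wobbles in 1-12 weigh 3.0 > 2.5
        cls = align_site(
            MIRNA, complement_window(MIRNA, wobble_at=[1, 2, 4, 6, 9, 12])
        )
        verdicts, _ = check_rules(cls)
        assert not verdicts["max_mm_1_12"]


class TestScanUtrs:
    def test_planted_site_found_at_offset(self):
        rng = np.random.default_rng(12)
        flank = "".join(rng.choice(list("ACGT"), size=40))
        utr = flank + complement_window(MIRNA) + flank
        sites = scan_utrs({"m": MIRNA}, {"g": utr})
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (40, 62)
        assert sites[0].mfe_ratio == pytest.approx(1.0)

    def test_positive_and_decoy_fixture(self):
        """The constructed UTR set yields exactly the planted positives;
        every decoy (each violating exactly one rule) is rejected."""
        mirnas, utrs, expect = target_rule_fixture()
        sites = scan_utrs(mirnas, utrs)
        accepted = {s.gene_id for s in sites}
        positives = {g for g, label in expect.items() if label == "positive"}
        assert accepted == positives
        # and each decoy fails precisely its designated rule
        all_sites = scan_utrs(mirnas, utrs, keep_rejected=True)
        for gene, label in expect.items():
            if label == "positive":
                continue
            best = min(
                (s for s in all_sites if s.gene_id == gene),
                key=lambda s: sum(not v for v in s.rule_verdicts.values()),
            )
            fails = [r for r, v in best.rule_verdicts.items() if not v]
            assert fails == [label], gene

    def test_short_utr_skipped(self, caplog):
        sites = scan_utrs({"m": MIRNA}, {"g": "ACGT"})
        assert sites == []

    def test_empty_mirna_set(self):
        assert scan_utrs({}, {"g": "ACGT" * 30}) == []

    def test_matches_bruteforce_reference(self):
        """Independent per-window re-evaluation agrees with scan_utrs on
        random UTRs (acceptance parity of every window)."""
        rng = np.random.default_rng(13)
        mirna = MIRNA
        utrs = {}
        for g in range(6):
            utr = "".join(rng.choice(list("ACGT"), size=120))
            if g < 3:  # embed a near-perfect site
                w = complement_window(mirna, mismatch_at=[20])
                utr = utr[:30] + w + utr[30 + len(w):]
            utrs[f"g{g}"] = utr
        got = {(s.gene_id, s.start) for s in scan_utrs({"m": mirna}, utrs)}

        # brute force, written independently of the implementation
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        want = set()
        L = len(mirna)
        pce = perfect_complement_energy(mirna)
        for gene, utr in utrs.items():
            for off in range(len(utr) - L + 1):
                win = utr[off : off + L]
                kinds = []
                for i in range(L):
                    a, b = mirna[i], win[L - 1 - i]
                    if comp[a] == b:
                        kinds.append(0)  # WC
                    elif (a, b) in (("G", "T"), ("T", "G")):
                        kinds.append(1)  # wobble
                    else:
                        kinds.append(2)  # mismatch
                score = sum(1.0 if k == 2 else (0.5 if k == 1 else 0.0) for k in kinds)
                mmpos = [k != 0 for k in kinds]
                runs = max(
                    (len(r) for r in "".join("x" if f else "." for f in mmpos).split(".")),
                    default=0,
                )
                seed_adj = any(mmpos[i] and mmpos[i + 1] for i in range(1, 11))
                core = mmpos[9] or mmpos[10]
                seed_score = sum(
                    1.0 if k == 2 else (0.5 if k == 1 else 0.0) for k in kinds[:12]
                )
                energy = duplex_energy(mirna, win)
                ok = (
                    score <= 4
                    and runs <= 2
                    and not seed_adj
                    and not core
                    and seed_score <= 2.5
                    and abs(energy) / abs(pce) >= 0.75
                )
                if ok:
                    want.add((gene, off))
        assert got == want

    def test_acceptance_monotone_in_thresholds(self):
        mirnas, utrs, _ = target_rule_fixture()
        strict = {(s.mirna_id, s.gene_id, s.start) for s in scan_utrs(mirnas, utrs)}
        loose_rules = TargetRules(
            max_mismatches=5.0, max_adjacent_mm=3, max_mm_1_12=3.0, min_mfe_ratio=0.6
        )
        loose = {
            (s.mirna_id, s.gene_id, s.start)
            for s in scan_utrs(mirnas, utrs, loose_rules)
        }
        assert strict <= loose
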