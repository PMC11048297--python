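"""Shared fixtures: a hand-enumerated 20-site toy cascade dataset and small
simulation helpers used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def _obs_row(sample, chrom, pos, strand, ref_reads, alt_reads):
    ref_base = "A" if strand == "+" else "T"
    return (sample, chrom, pos, strand, ref_base, ref_reads, alt_reads)


@pytest.fixture(scope="session")
def toy_cascade():
    """20 sites, 4 samples, every filter-cascade stage exercised.

    Expected accounting (thresholds: >=5 edited reads, AF >= 0.05,
    prevalence strictly > 50% of 4 samples, exact-allele variant match),
    enumerated by hand:

    * candidate call removes S2 (alt 4 < 5), S3 (AF 0.029), S9 (alt 1),
      S15 (AF 0.04), S16 (alt 4)                                -> 20 - 5 = 15
    * prevalence removes S5 (2/4), S8 (1/4), S13 (2/4), S20 (2/4
      boundary: exactly 50% is NOT > 50%)                       -> 15 - 4 = 11
    * variant subtraction removes S6 (chr1:600 A>G hit) and S11
      (chr1:1100 T>C hit); chr1:1000 A>T (allele mismatch),
      chr1:1200 A>G (strand-allele mismatch on a - site),
      chr2:1700 (chrom mismatch), chr1:999 (no site) all miss   -> 11 - 2 = 9

    Survivors: S1 S4 S7 S10 S12 S14 S17 S18 S19.
    """
    rows = []
    # S1 pos 100: boundary-pass in all samples (alt=5, AF=0.05)
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 100, "+", 95, 5))
    # S2 pos 200: alt=4 < 5 despite AF 0.5
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 200, "+", 4, 4))
    # S3 pos 300: AF ~0.029 < 0.05 despite alt=6
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 300, "+", 200, 6))
    # S4 pos 400: called in s1; s2 covered ref-only; s3 sub-threshold; s4 missing
    rows += [
        _obs_row("s1", "chr1", 400, "+", 50, 50),
        _obs_row("s2", "chr1", 400, "+", 60, 0),
        _obs_row("s3", "chr1", 400, "+", 40, 2),
    ]
    # S5 pos 500: called in s1 but covered in only 2/4 samples
    rows += [
        _obs_row("s1", "chr1", 500, "+", 20, 10),
        _obs_row("s4", "chr1", 500, "+", 30, 1),
    ]
    # S6 pos 600: called, fully covered, but a planted DNA variant
    rows += [
        _obs_row("s1", "chr1", 600, "+", 10, 5),
        _obs_row("s2", "chr1", 600, "+", 50, 3),
        _obs_row("s3", "chr1", 600, "+", 60, 0),
        _obs_row("s4", "chr1", 600, "+", 70, 2),
    ]
    # S7 pos 700: called in s2, fully covered
    rows += [
        _obs_row("s1", "chr1", 700, "+", 80, 1),
        _obs_row("s2", "chr1", 700, "+", 90, 10),
        _obs_row("s3", "chr1", 700, "+", 85, 0),
        _obs_row("s4", "chr1", 700, "+", 75, 2),
    ]
    # S8 pos 800: called but covered in 1/4 samples only
    rows.append(_obs_row("s1", "chr1", 800, "+", 95, 5))
    # S9 pos 900: never called (alt=1 everywhere)
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 900, "+", 100, 1))
    # S10 pos 1000: called everywhere; variant at same pos has wrong alt allele
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1000, "+", 10, 90))
    # S11 pos 1100 (- strand): called everywhere; T>C variant removes it
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1100, "-", 90, 10))
    # S12 pos 1200 (- strand): called; A>G variant does NOT match a T>C site
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1200, "-", 80, 20))
    # S13 pos 1300: called in s1; covered 2/4
    rows += [
        _obs_row("s1", "chr1", 1300, "+", 45, 5),
        _obs_row("s2", "chr1", 1300, "+", 30, 0),
    ]
    # S14 pos 1400: called in s1 (alt=5, AF 0.5); covered 3/4
    rows += [
        _obs_row("s1", "chr1", 1400, "+", 5, 5),
        _obs_row("s2", "chr1", 1400, "+", 8, 0),
        _obs_row("s3", "chr1", 1400, "+", 12, 1),
    ]
    # S15 pos 1500: AF 0.04 < 0.05 despite alt=5
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1500, "+", 120, 5))
    # S16 pos 1600: alt=4 < 5 despite AF 0.09
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1600, "+", 40, 4))
    # S17 pos 1700: called; variant on a different chromosome misses
    for s in ("s1", "s2", "s3", "s4"):
        rows.append(_obs_row(s, "chr1", 1700, "+", 70, 30))
    # S18 pos 1800: called in s3 only but covered everywhere
    rows += [
        _obs_row("s1", "chr1", 1800, "+", 60, 1),
        _obs_row("s2", "chr1", 1800, "+", 70, 0),
        _obs_row("s3", "chr1", 1800, "+", 55, 6),
        _obs_row("s4", "chr1", 1800, "+", 65, 2),
    ]
    # S19 pos 1900: fully edited in s4 (ref=0 is valid), covered everywhere
    rows += [
        _obs_row("s1", "chr1", 1900, "+", 10, 0),
        _obs_row("s2", "chr1", 1900, "+", 12, 0),
        _obs_row("s3", "chr1", 1900, "+", 15, 0),
        _obs_row("s4", "chr1", 1900, "+", 0, 10),
    ]
    # S20 pos 2000: called in s1; covered exactly 50% (boundary removal)
    rows += [
        _obs_row("s1", "chr1", 2000, "+", 20, 80),
        _obs_row("s2", "chr1", 2000, "+", 30, 0),
    ]

    obs = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "strand", "ref_base", "ref_reads", "alt_reads"],
    )
    variants = {
        ("chr1", 600, "A", "G"),
        ("chr1", 1000, "A", "T"),
        ("chr1", 1100, "T", "C"),
        ("chr1", 1200, "A", "G"),
        ("chr2", 1700, "A", "G"),
        ("chr1", 999, "A", "G"),
    }
    expected = {
        "stages": {
            "candidate_call": (20, 5, 15),
            "resolve_missing": (15, 0, 15),
            "prevalence": (15, 4, 11),
            "variant_subtraction": (11, 2, 9),
        },
        "survivors": {
            "chr1:100:+", "chr1:400:+", "chr1:700:+", "chr1:1000:+",
            "chr1:1200:-", "chr1:1400:+", "chr1:1700:+", "chr1:1800:+",
            "chr1:1900:+",
        },
    }
    return obs, variants, expected


def simulate_bb_group(rng, n_samples, mu, rho, cov_mean=50.0, cov_disp=5.0):
    """(alt, total) cells with beta-binomial counts and NB coverage >= 1."""
    p = cov_disp / (cov_disp + cov_mean)
    n = np.maximum(rng.negative_binomial(cov_disp, p, n_samples), 1)
    if rho == 0:
        k = rng.binomial(n, mu)
    else:
        a, b = mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho
        k = rng.binomial(n, rng.beta(a, b, n_samples))
    return np.column_stack([k, n])


def brute_force_bh(pvalues):
    """Step-up BH q-values straight from the definition (test oracle)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def brute_force_logrank(labels, times, events):
    """Two-sample log-rank chi-square from the O-E / V definition (oracle)."""
    labels = np.asarray(labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1 = labels == labels[np.argsort(labels, kind="stable")][0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


def brute_force_km(times, events):
    """Product-limit survival at each distinct event time (oracle)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n
        out.append((t, s))
    return out
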