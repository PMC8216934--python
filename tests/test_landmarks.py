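"""Landmark rules: scripted cases, exclusions, and a brute-force oracle."""

import numpy as np
import pytest

from spinethrust import (
    BranchShapeParams,
    NormalizedContour,
    SmoothingParams,
    assign_landmarks,
    curvature_profile,
    detect_landmarks,
    find_extrema,
    generate_branch_contour,
)
from spinethrust.landmarks import Extremum, estimate_midline


def mk(seq):
    """Build an extremum list from (s_norm, value, kind-letter) triples."""
    return [
        Extremum(index=i, s_norm=s, value=v, kind="maximum" if k == "M" else "minimum")
        for i, (s, v, k) in enumerate(sorted(seq))
    ]


def oracle_assign(extrema, midline=0.475):
    """Independent, literal transcription of the assignment rules.

    Deliberately structured as explicit scans (no shared helpers with the
    implementation): pick the maximum nearest the midline, the deepest
    minima on either side of it, the maxima nearest outside the deep
    minima, then re-seat the central maximum if several lie between the
    two minima.  Returns five extrema or the first missing role name.
    """
    maxima = [e for e in extrema if e.kind == "maximum"]
    minima = [e for e in extrema if e.kind == "minimum"]

    def closest(cands, target):
        best = None
        for e in cands:
            d = abs(e.s_norm - target)
            if best is None or d < best[0] or (d == best[0] and e.index < best[1].index):
                best = (d, e)
        return best[1]

    def lowest(cands):
        best = None
        for e in cands:
            if best is None or e.value < best.value or (
                e.value == best.value and e.index < best.index
            ):
                best = e
        return best

    if not maxima:
        return "missing-L3"
    l3 = closest(maxima, midline)
    left_min = [e for e in minima if e.index < l3.index]
    if not left_min:
        return "missing-L2"
    l2 = lowest(left_min)
    left_max = [e for e in maxima if e.index < l2.index]
    if not left_max:
        return "missing-L1"
    l1 = closest(left_max, l2.s_norm)
    right_min = [e for e in minima if e.index > l3.index]
    if not right_min:
        return "missing-L4"
    l4 = lowest(right_min)
    right_max = [e for e in maxima if e.index > l4.index]
    if not right_max:
        return "missing-L5"
    l5 = closest(right_max, l4.s_norm)
    between = [e for e in maxima if l2.index < e.index < l4.index]
    if len(between) > 1:
        top = None
        for e in between:
            if top is None or e.value > top.value:
                top = e
        l3 = top
    return (l1, l2, l3, l4, l5)


class TestFindExtrema:
    def test_sine_profile_two_periods(self, params):
        # a clean oscillation: every interior extremum is found
        s = np.linspace(0, 4 * np.pi, 400)
        prof = _profile_with(np.sin(s))
        found = find_extrema(prof, SmoothingParams(exclusion_fraction=0.0))
        kinds = [e.kind for e in found]
        assert kinds.count("maximum") == 2 and kinds.count("minimum") == 2

    def test_monotone_profile_empty(self, params):
        prof = _profile_with(np.linspace(0, 1, 200))
        assert find_extrema(prof, params) == []

    def test_exclusion_window_filters_early_extrema(self):
        k = np.zeros(200)
        k[20] = 1.0  # spike at s_norm ~ 0.10
        k[100] = 1.0  # spike at s_norm ~ 0.50
        prof = _profile_with(k)
        found = find_extrema(prof, SmoothingParams(exclusion_fraction=0.20))
        assert [round(e.s_norm, 2) for e in found if e.kind == "maximum"] == [0.5]

    def test_plateau_reports_first_index(self):
        k = np.zeros(100)
        k[40:45] = 1.0
        prof = _profile_with(k)
        found = find_extrema(prof, SmoothingParams(exclusion_fraction=0.0))
        assert [e.index for e in found if e.kind == "maximum"] == [40]


def _profile_with(k):
    """Wrap a raw k array in a minimal CurvatureProfile for extremum tests."""
    from spinethrust.curvature import CurvatureProfile

    L = len(k) + 2 + 2  # pretend beta margin of 1 on each side
    return CurvatureProfile(
        s=np.arange(L, dtype=float),
        k_raw=np.zeros(L - 2),
        n_raw=L,
        k_refined=np.zeros(L - 2),
        k_smoothed=np.asarray(k, dtype=float),
        margins={"alpha": 1, "raw": 1, "beta": 1},
    )


SCRIPTED_CASES = [
    # (extrema, expected s_norms of L1..L5 or exclusion reason)
    (
        [(0.30, 2, "M"), (0.38, -1, "m"), (0.48, 1, "M"), (0.56, -1, "m"), (0.65, 2, "M")],
        [0.30, 0.38, 0.48, 0.56, 0.65],
    ),
    # no minimum left of the central maximum
    (
        [(0.30, 2, "M"), (0.48, 1, "M"), (0.56, -1, "m"), (0.65, 2, "M")],
        "missing-L2",
    ),
    # central-landmark resampling to the highest maximum between the cavities
    (
        [
            (0.30, 2, "M"), (0.38, -1, "m"), (0.45, 1.0, "M"), (0.50, 1.8, "M"),
            (0.56, -1, "m"), (0.65, 2, "M"),
        ],
        [0.30, 0.38, 0.50, 0.56, 0.65],
    ),
    # the deepest (not the nearest) left minimum becomes landmark 2
    (
        [
            (0.25, 2, "M"), (0.33, -0.5, "m"), (0.36, -1.2, "m"), (0.48, 1, "M"),
            (0.56, -1, "m"), (0.65, 2, "M"),
        ],
        [0.25, 0.36, 0.48, 0.56, 0.65],
    ),
    # no maximum outside the left cavity
    (
        [(0.38, -1, "m"), (0.48, 1, "M"), (0.56, -1, "m"), (0.65, 2, "M")],
        "missing-L1",
    ),
    # nothing right of the central maximum
    (
        [(0.30, 2, "M"), (0.38, -1, "m"), (0.48, 1, "M")],
        "missing-L4",
    ),
    # a right cavity but no maximum beyond it
    (
        [(0.30, 2, "M"), (0.38, -1, "m"), (0.48, 1, "M"), (0.56, -1, "m")],
        "missing-L5",
    ),
    # no maxima at all
    ([(0.38, -1, "m"), (0.56, -1, "m")], "missing-L3"),
]


class TestAssignLandmarks:
    @pytest.mark.parametrize("seq,expected", SCRIPTED_CASES)
    def test_scripted_cases(self, seq, expected, params):
        out = assign_landmarks(mk(seq), params)
        if isinstance(expected, str):
            assert out.status == "excluded" and out.reason == expected
        else:
            assert out.status == "valid"
            assert [round(lm.s_norm, 2) for lm in out.landmarks] == expected

    @pytest.mark.parametrize("seq,expected", SCRIPTED_CASES)
    def test_matches_brute_force_oracle(self, seq, expected, params):
        ext = mk(seq)
        got = assign_landmarks(ext, params)
        want = oracle_assign(ext, params.midline_position)
        if isinstance(want, str):
            assert got.status == "excluded" and got.reason == want
        else:
            assert got.status == "valid"
            assert [lm.index for lm in got.landmarks] == [e.index for e in want]

    def test_random_sequences_match_oracle(self, params):
        rng = np.random.default_rng(2024)
        agree = 0
        n_cases = 300
        for _ in range(n_cases):
            n = rng.integers(0, 12)
            s = np.sort(rng.uniform(0.2, 0.8, n))
            ext = [
                Extremum(
                    index=i,
                    s_norm=float(s[i]),
                    value=float(np.round(rng.uniform(-2, 2), 1)),
                    kind="maximum" if rng.random() < 0.5 else "minimum",
                )
                for i in range(n)
            ]
            got = assign_landmarks(ext, params)
            want = oracle_assign(ext, params.midline_position)
            if isinstance(want, str):
                agree += got.status == "excluded" and got.reason == want
            else:
                agree += got.status == "valid" and [
                    lm.index for lm in got.landmarks
                ] == [e.index for e in want]
        assert agree == n_cases

    def test_determinism(self, params):
        ext = mk(SCRIPTED_CASES[0][0])
        a = assign_landmarks(ext, params)
        b = assign_landmarks(ext, params)
        assert [l.index for l in a.landmarks] == [l.index for l in b.landmarks]


class TestDetectOnSynthetic:
    def test_landmarks_near_ground_truth(self, branch_specimen, params):
        sc, prof = curvature_profile(branch_specimen.contour, params)
        out = detect_landmarks(sc, prof, params)
        assert out.status == "valid"
        got = out.landmarks.coordinates()
        true = branch_specimen.true_landmarks.coordinates()
        # within the smoothing margin: positions shift by < 1 um
        assert np.max(np.abs(got[:, 0] - true[:, 0])) < 1.0

    def test_ordering_and_window_invariants(self, branch_specimen, params):
        sc, prof = curvature_profile(branch_specimen.contour, params)
        out = detect_landmarks(sc, prof, params)
        s = [lm.s_norm for lm in out.landmarks]
        assert all(a < b for a, b in zip(s[:-1], s[1:]))
        assert all(
            params.exclusion_fraction <= v <= 1 - params.exclusion_fraction for v in s
        )

    def test_oversmoothed_profile_is_excluded_not_imputed(self, branch_specimen):
        # beta large enough to erase the spine maxima: the specimen must
        # come back excluded with a named missing role
        params = SmoothingParams(alpha=0.025, beta=0.2)
        sc, prof = curvature_profile(branch_specimen.contour, params)
        out = detect_landmarks(sc, prof, params)
        assert out.status == "excluded"
        assert out.reason.startswith("missing-L")


def test_estimate_midline_centers_on_ridge_dominant_shapes(params):
    # the helper keys on the global curvature maximum, so it is meaningful
    # for rounded forms whose central ridge is the sharpest feature
    profiles = []
    for seed in range(3):
        sp = generate_branch_contour(
            BranchShapeParams(spine_height=1.5, ridge_height=5.0, seed=seed)
        )
        _, prof = curvature_profile(sp.contour, params)
        profiles.append(prof)
    assert 0.4 < estimate_midline(profiles) < 0.6
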