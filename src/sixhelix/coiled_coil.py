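"""Helix detection, bundle axes, heptad registers and stutter detection.

A coiled coil repeats seven residues (letters a-g) every two helix turns, so
the Crick phase - the azimuth of each CA about its local helix axis, measured
from the direction pointing at the bundle core - advances by 720/7 = 102.857
degrees per residue. The seven ideal letter phases form a uniform grid spaced
360/7 = 51.43 degrees, with a and d flanking the core direction.

A stutter inserts one extra four-residue repeat (canonically "defg") into the
pattern, producing local 11/3 periodicity: over the four inserted residues the
phase falls behind the canonical line by exactly one grid step (51.43 deg).
Register assignment therefore fits the unwrapped phase to a canonical line
plus an optional four-residue slip ramp; the changepoint position of the ramp
is the stutter span. This is robust to the gradual local unwinding real
stutters show, where per-residue nearest-letter assignment is ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

LETTERS = "abcdefg"
PHASE_STEP = 720.0 / 7.0          # deg per residue, canonical heptad
GRID = 360.0 / 7.0                # spacing of ideal letter phases
SLIP = GRID                       # phase deficit introduced by one stutter
#: ideal Crick phase of each register letter; a/d straddle the inward direction
IDEAL_PHASE = {LETTERS[k]: (GRID / 2.0 + PHASE_STEP * k) % 360.0 for k in range(7)}

HYDROPHOBIC = set("AVLIMFWC")
ACIDIC = set("DE")
BASIC = set("KRH")


def residue_class(aa: str) -> str:
    if aa in HYDROPHOBIC:
        return "hydrophobic"
    if aa in ACIDIC:
        return "acidic"
    if aa in BASIC:
        return "basic"
    return "polar"


@dataclass
class HelixSegment:
    """A maximal alpha-helical run of >= 7 residues in one chain."""

    chain_id: str
    numbers: list[int]            # author numbers, N -> C
    ca: np.ndarray                # (n, 3)

    @property
    def start(self) -> int:
        return self.numbers[0]

    @property
    def end(self) -> int:
        return self.numbers[-1]

    def __len__(self) -> int:
        return len(self.numbers)

    @property
    def turns(self) -> float:
        """Approximate helix-turn count (3.6 residues per alpha turn)."""
        return len(self.numbers) / 3.6

    def axis_polyline(self) -> np.ndarray:
        """Local helix-axis points a_i for residues 2 .. n-3 (moving-average
        of four consecutive CA midpoints); ordered N -> C."""
        p = self.ca
        m = (p[:-3] + p[1:-2] + p[2:-1] + p[3:]) / 4.0      # centered at i+1.5
        return (m[:-1] + m[1:]) / 2.0                        # centered at i+2

    def direction(self) -> np.ndarray:
        ax = self.axis_polyline()
        d = ax[-1] - ax[0]
        return d / np.linalg.norm(d)


@dataclass
class BundleAxis:
    """Least-squares line through the helix-axis points of a bundle."""

    point: np.ndarray
    direction: np.ndarray

    def axial(self, pos: np.ndarray) -> np.ndarray:
        """Signed axial coordinate (A) of point(s) along the bundle axis."""
        return np.asarray(pos - self.point) @ self.direction

    def radial(self, pos: np.ndarray) -> np.ndarray:
        """Distance (A) of point(s) from the axis line."""
        rel = np.atleast_2d(np.asarray(pos) - self.point)
        perp = rel - np.outer(rel @ self.direction, self.direction)
        r = np.linalg.norm(perp, axis=1)
        return r if r.size > 1 else float(r[0])


@dataclass
class HeptadAssignment:
    """Per-residue register letters with declared stutter spans for one helix."""

    chain_id: str
    numbers: list[int]
    letters: str
    phases: np.ndarray            # unwrapped measured Crick phase, deg
    stutter_spans: list[tuple[int, int]] = field(default_factory=list)

    def letter_of(self, number: int) -> str:
        return self.letters[self.numbers.index(number)]


@dataclass
class WheelPosition:
    number: int
    residue: str
    letter: str
    phys_class: str
    stutter: bool


@dataclass
class HelicalWheel:
    start: int
    end: int
    positions: list[WheelPosition]


def assign_helices(
    model,
    d13: tuple[float, float] = (4.5, 5.7),
    d14: tuple[float, float] = (5.7, 6.9),
    min_len: int = 7,
) -> list[HelixSegment]:
    """Maximal runs of residues whose CA(i)-CA(i+3) and CA(i)-CA(i+4)
    distances fall in alpha-helical ranges.

    The distance series are median-filtered (window 5) before thresholding so
    that moderate coordinate noise does not fragment a genuine helix.
    """
    from scipy.ndimage import median_filter

    segments: list[HelixSegment] = []
    for chain in model.chains:
        coords, numbers = [], []
        for res in chain.residues:
            ca = res.get_atom("CA")
            if ca is None:
                warnings.warn(
                    f"{chain.chain_id}/{res.number} {res.name}: no CA, skipped"
                )
                continue
            coords.append(ca.pos)
            numbers.append(res.number)
        p = np.asarray(coords).reshape(-1, 3)
        n = len(p)
        if n < min_len:
            continue
        a = np.linalg.norm(p[:-3] - p[3:], axis=1)
        b = np.linalg.norm(p[:-4] - p[4:], axis=1)
        a = median_filter(a[: n - 4], size=5, mode="nearest")
        b = median_filter(b, size=5, mode="nearest")
        ok = np.zeros(n, dtype=bool)
        ok[: n - 4] = ((d13[0] <= a) & (a <= d13[1])
                       & (d14[0] <= b) & (b <= d14[1]))
        # close isolated 1-2 residue violations inside a helical run
        for i in range(1, n - 5):
            if not ok[i] and ok[i - 1] and (ok[i + 1] or (i + 2 < n - 4 and ok[i + 2])):
                ok[i] = True
        i = 0
        while i < n - 4:
            if not ok[i]:
                i += 1
                continue
            j = i
            while j + 1 < n - 4 and ok[j + 1]:
                j += 1
            if j + 4 - i + 1 >= min_len:
                segments.append(
                    HelixSegment(
                        chain_id=chain.chain_id,
                        numbers=numbers[i : j + 5],
                        ca=p[i : j + 5],
                    )
                )
            i = j + 1
    return segments


def fit_bundle_axis(
    segments: list[HelixSegment], max_angle: float = 40.0
) -> BundleAxis:
    """Least-squares line through the local helix-axis points of >= 2 roughly
    parallel or antiparallel segments."""
    if len(segments) < 2:
        raise ValueError("a bundle axis needs at least two helix segments")
    dirs = [s.direction() for s in segments]
    for i in range(len(dirs)):
        for j in range(i + 1, len(dirs)):
            ang = np.degrees(np.arccos(np.clip(abs(dirs[i] @ dirs[j]), -1, 1)))
            if ang > max_angle:
                raise ValueError(
                    f"segments {i} and {j} are {ang:.0f} deg apart: not a bundle"
                )
    pts = np.vstack([s.axis_polyline() for s in segments])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    direction = vt[0]
    if direction @ dirs[0] < 0:
        direction = -direction
    direction, centroid = _refine_cylinder_axis(pts, centroid, direction)
    return BundleAxis(point=centroid, direction=direction)


def _refine_cylinder_axis(pts: np.ndarray, point: np.ndarray,
                          direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Refine an axis estimate by minimizing the variance of the points'
    radial distances (the helix-axis points of a bundle lie on a cylinder
    around the bundle axis).

    A plain principal-axis fit is biased when the segments cover unequal
    axial ranges; the cylinder objective is not.
    """
    from scipy.optimize import minimize

    # orthonormal frame around the initial direction
    u = np.cross(direction, [1.0, 0.0, 0.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(direction, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)

    def unpack(x):
        d = direction + x[0] * u + x[1] * v
        d /= np.linalg.norm(d)
        p = point + x[2] * u + x[3] * v
        return d, p

    def objective(x):
        d, p = unpack(x)
        rel = pts - p
        perp = rel - np.outer(rel @ d, d)
        r = np.linalg.norm(perp, axis=1)
        return np.var(r)

    res = minimize(objective, np.zeros(4), method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 2000})
    d, p = unpack(res.x)
    if d @ direction < 0:
        d = -d
    return d, p


def crick_phases(segment: HelixSegment, axis: BundleAxis) -> tuple[np.ndarray, list[int]]:
    """Unwrapped Crick phase (deg) for residues 2 .. n-3 of a segment.

    Phase 0 points from the local helix axis toward the bundle axis; positive
    sense is right-handed about the chain direction.
    """
    ax = segment.axis_polyline()          # residues 2 .. n-3
    nums = segment.numbers[2:-3]
    ca = segment.ca[2:-3]
    tang = np.gradient(ax, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)

    raw = np.empty(len(ca))
    for i in range(len(ca)):
        t = tang[i]
        # inward reference: from local axis point toward the bundle axis line
        rel = axis.point - ax[i]
        rel_par = (rel @ axis.direction) * axis.direction
        u = rel - rel_par
        u -= (u @ t) * t
        nu = np.linalg.norm(u)
        if nu < 1e-6:
            raise ValueError("helix lies on the bundle axis; phase undefined")
        u /= nu
        v = ca[i] - ax[i]
        v -= (v @ t) * t
        w = np.cross(t, u)
        raw[i] = np.degrees(np.arctan2(v @ w, v @ u)) % 360.0

    # unwrap assuming forward advance in (0, 360) per residue
    phases = np.empty_like(raw)
    phases[0] = raw[0]
    for i in range(1, len(raw)):
        step = (raw[i] - raw[i - 1]) % 360.0
        phases[i] = phases[i - 1] + step
    return phases, list(nums)


#: the stutter's 51.43 deg slip develops over ~two helix turns (8 residues)
#: centred on the 4-residue span - the local 11/3 unwinding is gradual
SLIP_WINDOW = 8


def _slip_ramp(n: int, k: int) -> np.ndarray:
    """Cumulative phase deficit of a stutter whose 4-residue span starts at
    index k: a linear ramp over SLIP_WINDOW residues centred on the span."""
    i = np.arange(n)
    return (SLIP / SLIP_WINDOW) * np.clip(i - (k - 2), 0, SLIP_WINDOW)


def _fit_phase_model(phases: np.ndarray, max_stutters: int = 3,
                     min_rms: float = 8.0,
                     accept_ratio: float = 0.5) -> tuple[float, float, list[int]]:
    """Fit phases ~ c + PHASE_STEP*i - sum of slip ramps by greedy changepoint
    search.

    A candidate stutter is accepted only when it removes at least half of the
    residual variance and the residual exceeds the noise floor (``min_rms``
    deg). Returns (offset c, reserved slope 0.0, sorted stutter start
    indices).
    """
    n = len(phases)
    i = np.arange(n, dtype=float)
    base_line = PHASE_STEP * i

    def fit(ks: list[int]) -> tuple[float, float]:
        target = phases - base_line + sum((_slip_ramp(n, k) for k in ks),
                                          np.zeros(n))
        c = target.mean()
        return float(np.sum((target - c) ** 2)), float(c)

    ks: list[int] = []
    cur_ss, c = fit(ks)
    for _ in range(max_stutters):
        if np.sqrt(cur_ss / n) <= min_rms:
            break
        best = None
        for k in range(1, n - 3):
            if any(abs(k - k0) < 4 for k0 in ks):
                continue
            ss, cc = fit(ks + [k])
            if best is None or ss < best[0]:
                best = (ss, cc, k)
        if best is None or best[0] > accept_ratio * cur_ss:
            break
        cur_ss, c, k = best
        ks.append(k)
    return c, 0.0, sorted(ks)


def _letters_from_model(n: int, c: float, beta: float, ks: list[int]) -> str:
    """Discrete register letters implied by the fitted phase model.

    The base letter is quantized at a residue outside every slip ramp (the
    model phase sits on the letter grid only there), preferring one near the
    chain centre; letters advance canonically with the previous four repeated
    at each stutter span.
    """
    candidates = [i for i in range(n)
                  if all(not (k - 2 <= i <= k + 6) for k in ks)] or [n // 2]
    mid = min(candidates, key=lambda i: abs(i - n // 2))
    shift_mid = 4 * sum(1 for k in ks if mid >= k)
    phase_mid = (c + (PHASE_STEP + beta) * mid
                 - sum(_slip_ramp(n, k)[mid] for k in ks))
    ideals = np.array([IDEAL_PHASE[l] for l in LETTERS])
    diffs = np.abs((phase_mid % 360.0) - ideals)
    diffs = np.minimum(diffs, 360.0 - diffs)
    letter_mid = int(np.argmin(diffs))
    base = (letter_mid - mid + shift_mid) % 7
    out = []
    for i in range(n):
        shift = 4 * sum(1 for k in ks if i >= k)
        out.append(LETTERS[(base + i - shift) % 7])
    return "".join(out)


def assign_heptad_register(
    segments: list[HelixSegment],
    axis: BundleAxis | None = None,
    max_stutters: int = 3,
) -> list[HeptadAssignment]:
    """Geometric register assignment for the core helices of a bundle.

    Each segment's Crick phases are fitted to the canonical heptad line with
    optional stutter slips; letters come from the fitted model so that stutter
    spans carry their inserted repeat (canonically "defg").
    """
    if axis is None:
        axis = fit_bundle_axis(segments)
    out = []
    for seg in segments:
        phases, nums = crick_phases(seg, axis)
        if len(nums) < 7:
            raise ValueError("segment too short for register assignment")
        c, beta, ks = _fit_phase_model(phases, max_stutters=max_stutters)
        letters = _letters_from_model(len(nums), c, beta, ks)
        spans = [(nums[k], nums[k + 3]) for k in ks]
        out.append(
            HeptadAssignment(
                chain_id=seg.chain_id,
                numbers=nums,
                letters=letters,
                phases=phases,
                stutter_spans=spans,
            )
        )
    return out


def detect_stutters(assignment: HeptadAssignment) -> list[tuple[int, int]]:
    """Four-residue spans where the register requires one extra repeat
    (local 11/3 periodicity). Empty for a canonical register."""
    if len(assignment.numbers) < 14:
        raise ValueError("need at least two heptads to detect stutters")
    _, _, ks = _fit_phase_model(assignment.phases)
    return [(assignment.numbers[k], assignment.numbers[k + 3]) for k in ks]


def register_from_sequence(
    seq: str,
    numbers: list[int] | None = None,
    allow_stutter: bool = True,
    margin: float = 2.0,
) -> tuple[str, list[tuple[int, int]]]:
    """Sequence-only fallback register: choose the heptad offset (and optional
    stutter position) maximizing hydrophobic enrichment at a/d positions.

    Returns (letters, stutter spans in the provided numbering). A stutter is
    only called when it beats the best canonical assignment by ``margin``.

    The hydrophobic pattern cannot localize the insertion inside a run of
    non-core letters, so among equal-scoring positions the canonical "defg"
    insertion (span preceded by a g) is preferred, then the most N-terminal.
    """
    n = len(seq)
    if numbers is None:
        numbers = list(range(1, n + 1))

    def score(base: int, k: int | None) -> float:
        s = 0.0
        for i, aa in enumerate(seq):
            shift = 4 if (k is not None and i >= k) else 0
            letter = LETTERS[(base + i - shift) % 7]
            hyd = aa in HYDROPHOBIC
            if letter in "ad":
                s += 1.0 if hyd else -1.0
            elif hyd:
                s -= 0.25
        return s

    best_plain = max(score(b, None) for b in range(7))
    plain_base = max(range(7), key=lambda b: score(b, None))
    base, k = plain_base, None
    if allow_stutter and n >= 16:
        scored = [(score(b, kk), b, kk)
                  for b in range(7) for kk in range(4, n - 4)]
        top = max(s for s, _, _ in scored)
        if top >= best_plain + margin:
            ties = [(b, kk) for s, b, kk in scored if s >= top - 1e-9]
            canonical = [(b, kk) for b, kk in ties if (b + kk - 1) % 7 == 6]
            pool = canonical or ties
            base, k = min(pool, key=lambda t: t[1])
    ks = [] if k is None else [k]
    letters = "".join(
        LETTERS[(base + i - (4 if (k is not None and i >= k) else 0)) % 7]
        for i in range(n)
    )
    spans = [(numbers[kk], numbers[kk + 3]) for kk in ks]
    return letters, spans


def helical_wheel(
    seq: str,
    numbers: list[int],
    letters: str,
    stutter_spans: list[tuple[int, int]] | None = None,
    start: int | None = None,
    end: int | None = None,
) -> HelicalWheel:
    """Annotate a register window with physicochemical classes and stutter flags."""
    if not (len(seq) == len(numbers) == len(letters)):
        raise ValueError("seq, numbers and letters must have equal length")
    stutter_spans = stutter_spans or []
    start = numbers[0] if start is None else start
    end = numbers[-1] if end is None else end
    if start < numbers[0] or end > numbers[-1]:
        raise ValueError("window outside assigned region")
    positions = []
    for aa, num, letter in zip(seq, numbers, letters):
        if start <= num <= end:
            in_stutter = any(a <= num <= b for a, b in stutter_spans)
            positions.append(
                WheelPosition(num, aa, letter, residue_class(aa), in_stutter)
            )
    return HelicalWheel(start=start, end=end, positions=positions)
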