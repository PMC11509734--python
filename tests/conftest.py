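import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def dwc_file(tmp_path):
    """Small Darwin-Core-style tab-separated occurrence export."""
    rows = [
        "species\tinfraspecificEpithet\tdecimalLatitude\tdecimalLongitude\tyear\teventDate\tcountryCode\tbasisOfRecord",
        "Vespa velutina\tnigrithorax\t44.84\t-0.58\t2004\t2004-06-01\tFR\tHUMAN_OBSERVATION",
        "Vespa velutina\tnigrithorax\t44.85\t-0.57\t2005\t2005-07-12\tFR\tPRESERVED_SPECIMEN",
        "Vespa velutina\tvariana\t1.35\t103.82\t2003\t2003-03-03\tSG\tPRESERVED_SPECIMEN",
    ]
    p = tmp_path / "occ.tsv"
    p.write_text("\n".join(rows) + "\n")
    return p


def hull_area_oracle(points):
    """Independent O(n^3) convex-hull area: exhaustively verify extreme
    points via directed hull edges (all other points strictly left),
    then fan-triangulate from an angular sort.  Assumes points in
    general position (no 3 collinear), which random draws satisfy."""
    xy = np.unique(np.array([(lon, lat) for lat, lon in points], float), axis=0)
    n = len(xy)
    if n < 3:
        return 0.0
    extreme = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = xy[j] - xy[i]
            rel = xy - xy[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            mask = np.ones(n, bool)
            mask[[i, j]] = False
            if np.all(cross[mask] > 0):
                extreme.add(i)
                extreme.add(j)
    if len(extreme) < 3:
        return 0.0
    ext = xy[sorted(extreme)]
    ctr = ext.mean(axis=0)
    ang = np.arctan2(ext[:, 1] - ctr[1], ext[:, 0] - ctr[0])
    ext = ext[np.argsort(ang)]
    # fan from vertex 0: sum of triangle areas
    area = 0.0
    for a in range(1, len(ext) - 1):
        v1 = ext[a] - ext[0]
        v2 = ext[a + 1] - ext[0]
        area += abs(v1[0] * v2[1] - v1[1] * v2[0]) / 2.0
    return area
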