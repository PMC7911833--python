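import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_twin_cohort(counts_by_zyg, condition="gp", extra_conditions=()):
    """Twin-only cohort frame realising exact (N_c, N_d, N_00) per zygosity."""
    rows = []
    fam = 0
    for zyg, (nc, nd, n00) in counts_by_zyg.items():
        for (s1, s2), n in (((1, 1), nc), ((1, 0), nd), ((0, 0), n00)):
            for _ in range(n):
                fam += 1
                fid = f"T{fam:05d}"
                for role, s in (("twin1", s1), ("twin2", s2)):
                    rows.append(
                        dict(family_id=fid, role=role, zygosity=zyg,
                             sex="female", age=10.0, **{condition: s},
                             **{c: 0 for c in extra_conditions})
                    )
    df = pd.DataFrame(rows)
    for c in (condition, *extra_conditions):
        df[c] = df[c].astype("Int8")
    return df


@pytest.fixture
def toy_cohort_csv(tmp_path):
    """Two complete five-member families with all six condition columns."""
    lines = ["family_id,role,zygosity,sex,age,gp,migraine,headache,rap,lbp,pp"]
    for fid, zyg in (("A", "MZ"), ("B", "DZ")):
        for role, sex, age in (
            ("twin1", "female", 10), ("twin2", "female", 10),
            ("oldest_sibling", "male", 14), ("mother", "female", 41),
            ("father", "male", 44),
        ):
            zy = zyg if role.startswith("twin") else "NA"
            lines.append(f"{fid},{role},{zy},{sex},{age},1,0,0,0,NA,0")
    path = tmp_path / "toy.csv"
    path.write_text("\n".join(lines) + "\n")
    return path
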