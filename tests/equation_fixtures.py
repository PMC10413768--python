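"""Hand-computed evaluation points for every equation in the registry.

Each entry pins one equation at one subject to a value computed directly
from the published linear form, written out as inline arithmetic so the
expected value is independent of the registry/dispatch machinery it checks.
Energy conversions use the thermochemical factor: kJ/4.184, MJ*1000/4.184.
"""

KJ = 4.184  # kJ per kcal
MJ = 1000.0 / 4.184  # kcal per MJ


def case(eq, sex, age, weight, height, expected, ffm=None, fm=None):
    return {
        "eq": eq,
        "sex": sex,
        "age": age,
        "weight": weight,
        "height": height,
        "ffm": ffm,
        "fm": fm,
        "expected": expected,
    }


HAND_CASES = [
    # WHO/FAO/UNU, kcal/d, weight only, sex x age brackets
    case("who", "male", 12, 60, 150, (18.4 * 60) + 651),
    case("who", "female", 8, 30, 128, (22.5 * 30) + 499),
    case("who", "male", 6, 20, 115, (22.7 * 20) + 495),
    case("who", "female", 15, 50, 160, (12.5 * 50) + 746),
    # Schofield, kcal/d, weight + height(cm)
    case("schofield", "male", 8, 30, 130, (19.589 * 30) + (1.302 * 130) + 414.7),
    case("schofield", "female", 12, 50, 150, (8.361 * 50) + (4.654 * 150) + 200.0),
    case("schofield", "male", 15, 60, 170, (16.245 * 60) + (1.371 * 170) + 515.3),
    case("schofield", "female", 9, 28, 128, (16.961 * 28) + (1.617 * 128) + 371.0),
    # IOM, kcal/d, age + height(cm) + weight
    case("iom", "male", 12, 60, 150, 68 - (43.3 * 12) + (7.12 * 150) + (19.2 * 60)),
    case("iom", "female", 10, 40, 140, 189 - (17.6 * 10) + (6.25 * 140) + (7.9 * 40)),
    case("iom", "male", 7.5, 25, 120, 68 - (43.3 * 7.5) + (7.12 * 120) + (19.2 * 25)),
    # Kim, kcal/d, both sexes 4-11
    case("kim", "male", 8, 30, 130, 632.4 + (15.66 * 8) + (9.53 * 30)),
    case("kim", "female", 10.5, 40, 142, 632.4 + (15.66 * 10.5) + (9.53 * 40)),
    case("kim", "female", 5, 18, 110, 632.4 + (15.66 * 5) + (9.53 * 18)),
    # Henry, kcal/d
    case("henry", "male", 8, 30, 130, (15.1 * 30) + (0.742 * 130) + 306),
    case("henry", "female", 9, 28, 128, (15.9 * 28) + (2.1 * 128) + 349),
    case("henry", "male", 14, 55, 165, (15.6 * 55) + (2.66 * 165) + 299),
    case("henry", "female", 12, 45, 150, (9.40 * 45) + (2.49 * 150) + 462),
    # Molnar, kJ/d, sex coded male=0/female=1
    case("molnar", "female", 12, 50, 150,
         ((50.2 * 50) + (29.6 * 150) - (144.5 * 12) - (550 * 1) + 594.3) / KJ),
    case("molnar", "male", 14, 60, 170,
         ((50.2 * 60) + (29.6 * 170) - (144.5 * 14) - (550 * 0) + 594.3) / KJ),
    case("molnar", "male", 11, 40, 145,
         ((50.2 * 40) + (29.6 * 145) - (144.5 * 11) - (550 * 0) + 594.3) / KJ),
    # Muller weight/height form, MJ/d, sex coded male=0/female=1
    case("muller_a", "male", 10, 35, 140,
         ((0.02606 * 35) + (0.04129 * 140) + (0.311 * 0) - (0.08369 * 10) - 0.808) * MJ),
    case("muller_a", "female", 15, 55, 160,
         ((0.02606 * 55) + (0.04129 * 160) + (0.311 * 1) - (0.08369 * 15) - 0.808) * MJ),
    case("muller_a", "female", 7, 25, 122,
         ((0.02606 * 25) + (0.04129 * 122) + (0.311 * 1) - (0.08369 * 7) - 0.808) * MJ),
    # Muller FFM form, MJ/d
    case("muller_b", "male", 10, 50, 140, ffm=40, fm=10,
         expected=((0.07885 * 40) + (0.02132 * 10) + (0.327 * 0) + 2.694) * MJ),
    case("muller_b", "female", 12, 50, 150, ffm=35, fm=15,
         expected=((0.07885 * 35) + (0.02132 * 15) + (0.327 * 1) + 2.694) * MJ),
    case("muller_b", "male", 15, 70, 172, ffm=50, fm=20,
         expected=((0.07885 * 50) + (0.02132 * 20) + (0.327 * 0) + 2.694) * MJ),
    # Derumeaux-Burel, MJ/d, sex-free
    case("derumeaux_burel", "male", 12, 52, 150, ffm=40, fm=12,
         expected=((0.1371 * 40) - (0.1644 * 12) + 3.3647) * MJ),
    case("derumeaux_burel", "female", 8, 33, 128, ffm=25, fm=8,
         expected=((0.1371 * 25) - (0.1644 * 8) + 3.3647) * MJ),
    case("derumeaux_burel", "female", 16, 70, 165, ffm=55, fm=15,
         expected=((0.1371 * 55) - (0.1644 * 16) + 3.3647) * MJ),
    # Schmelzle, kcal/d, sex-specific
    case("schmelzle", "female", 12, 50, 150, (11.9 * 50) + (0.84 * 150) + 579),
    case("schmelzle", "male", 12, 45, 155, (6.6 * 45) + (13.1 * 155) - 794),
    case("schmelzle", "male", 8, 30, 130, (6.6 * 30) + (13.1 * 130) - 794),
    # Tverskaya, kcal/d, sex coded male=1/female=0
    case("tverskaya", "male", 12, 52, 150, ffm=40, fm=12,
         expected=775 + (28.4 * 40) - (37 * 12) + (3.3 * 12) + (82 * 1)),
    case("tverskaya", "female", 10, 40, 140, ffm=30, fm=10,
         expected=775 + (28.4 * 30) - (37 * 10) + (3.3 * 10) + (82 * 0)),
    case("tverskaya", "male", 16, 70, 172, ffm=55, fm=15,
         expected=775 + (28.4 * 55) - (37 * 16) + (3.3 * 15) + (82 * 1)),
    # Lazzer weight/height form, kJ/d, HEIGHT IN METERS, male=1/female=0
    case("lazzer_a", "male", 12, 60, 155,
         ((1 * 892.68) - (12 * 115.93) + (60 * 54.96) + (1.55 * 1816.23) + 1454.50) / KJ),
    case("lazzer_a", "female", 14, 55, 160,
         ((0 * 892.68) - (14 * 115.93) + (55 * 54.96) + (1.60 * 1816.23) + 1454.50) / KJ),
    case("lazzer_a", "male", 9, 35, 135,
         ((1 * 892.68) - (9 * 115.93) + (35 * 54.96) + (1.35 * 1816.23) + 1454.50) / KJ),
    # Lazzer FFM form, kJ/d, male=1/female=0
    case("lazzer_b", "male", 12, 60, 155, ffm=45, fm=15,
         expected=((1 * 909.12) - (12 * 107.48) + (45 * 68.39) + (15 * 55.19) + 3631.23) / KJ),
    case("lazzer_b", "female", 14, 56, 160, ffm=38, fm=18,
         expected=((0 * 909.12) - (14 * 107.48) + (38 * 68.39) + (18 * 55.19) + 3631.23) / KJ),
    case("lazzer_b", "female", 8, 30, 128, ffm=24, fm=6,
         expected=((0 * 909.12) - (8 * 107.48) + (24 * 68.39) + (6 * 55.19) + 3631.23) / KJ),
    # New FFM-based equation, kcal/d
    case("new_ffm", "female", 12, 57, 153, ffm=41.6, fm=15.2,
         expected=505.412 + (24.383 * 41.6)),
    case("new_ffm", "male", 10, 40, 140, ffm=0.0, fm=10,
         expected=505.412),
    case("new_ffm", "male", 16, 80, 175, ffm=60, fm=20,
         expected=505.412 + (24.383 * 60)),
]
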