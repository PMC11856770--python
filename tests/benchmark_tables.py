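"""Published per-class sample-division tables of the three benchmarks.

Each row: (class name, train, validation, test, total).  Split fractions are
10%/10% for Indian Pines and 1%/1% for Salinas and Pavia University.
"""

INDIAN_PINES = [
    ("Alfalfa", 4, 4, 38, 46),
    ("Corn-notill", 142, 128, 1158, 1428),
    ("Corn-mintill", 83, 74, 673, 830),
    ("Corn", 23, 21, 193, 237),
    ("Grass-pasture", 48, 43, 392, 483),
    ("Grass-trees", 73, 65, 592, 730),
    ("Grass-pasture-mowed", 2, 2, 24, 28),
    ("Hay-windrowed", 47, 43, 388, 478),
    ("Oats", 2, 1, 17, 20),
    ("Soybean-notill", 97, 87, 788, 972),
    ("Soybean-mintill", 245, 221, 1989, 2455),
    ("Soybean-clean", 59, 53, 481, 593),
    ("Wheat", 20, 18, 167, 205),
    ("Woods", 126, 113, 1026, 1265),
    ("Buildings-Grass-Trees-Drives", 38, 34, 314, 386),
    ("Stone-Steel-Towers", 9, 8, 76, 93),
]

SALINAS = [
    ("Brocoli_green_weeds_1", 20, 19, 1970, 2009),
    ("Brocoli_green_weeds_2", 37, 36, 3653, 3726),
    ("Fallow", 19, 19, 1938, 1976),
    ("Fallow_rough_plow", 13, 13, 1368, 1394),
    ("Fallow_smooth", 26, 26, 2626, 2678),
    ("Stubble", 39, 39, 3881, 3959),
    ("Celery", 35, 35, 3509, 3579),
    ("Grapes_untrained", 112, 111, 11048, 11271),
    ("Soil_vinyard_develop", 62, 61, 6080, 6203),
    ("Corn_senesced_green_weeds", 32, 32, 3214, 3278),
    ("Lettuce_romaine_4wk", 10, 10, 1048, 1068),
    ("Lettuce_romaine_5wk", 19, 19, 1889, 1927),
    ("Lettuce_romaine_6wk", 9, 9, 898, 916),
    ("Lettuce_romaine_7wk", 10, 10, 1050, 1070),
    ("Vinyard_untrained", 72, 71, 7125, 7268),
    ("Vinyard_vertical_trellis", 18, 17, 1772, 1807),
]

PAVIA_UNIVERSITY = [
    ("Asphalt", 66, 65, 6500, 6631),
    ("Meadows", 186, 184, 18279, 18649),
    ("Gravel", 20, 20, 2059, 2099),
    ("Trees", 30, 30, 3004, 3064),
    ("Painted metal sheets", 13, 13, 1319, 1345),
    ("Bare soil", 50, 49, 4930, 5029),
    ("Bitumen", 13, 13, 1304, 1330),
    ("Self-blocking bricks", 36, 36, 3610, 3682),
    ("Shadows", 9, 9, 929, 947),
]

TABLES = {
    "indian_pines": (INDIAN_PINES, (0.10, 0.10)),
    "salinas": (SALINAS, (0.01, 0.01)),
    "pavia_university": (PAVIA_UNIVERSITY, (0.01, 0.01)),
}
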