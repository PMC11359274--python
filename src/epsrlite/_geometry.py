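"""Frozen idealized Z-isomer indomethacin geometry.

Distance-geometry embedded and MMFF-optimized, then uniformly scaled so
the mean C-X (X = C, N, O) bond length is exactly 1.380 Angstrom.
Coordinates in Angstrom, centered on the molecular centroid.
"""

# (atom_type, element, x, y, z)
ATOMS = [
    ("C7", "C", -1.428677816253151, 1.8671267903918012, -0.1455708304212196),
    ("C2", "C", -0.39564562460023367, 0.8225666887672216, -0.03820513536278225),
    ("C3", "C", 0.8570325068993817, 0.9514055597016132, 0.4986273455887918),
    ("C1", "C", 1.5613054274969718, -0.227991605183557, 0.20518598732159032),
    ("C1", "C", 2.869518198687565, -0.6454361470622065, 0.45853097837166107),
    ("C1", "C", 3.2980375183594295, -1.882003859713335, 0.029107545561508078),
    ("C1", "C", 2.4299845328205953, -2.70022372657321, -0.6452659080459229),
    ("C1", "C", 1.1333485044671814, -2.313314123671437, -0.9073832707841206),
    ("C1", "C", 0.7102569966322912, -1.0627784935065583, -0.48021945712250275),
    ("N", "N", -0.5218730646472606, -0.44635563844853193, -0.5643321040048607),
    ("C4", "C", -1.6756531198941627, -1.0340946768077315, -1.0978437501342169),
    ("O3", "O", -1.5462742429717322, -1.9103275721197712, -1.9260274263941588),
    ("C9", "C", -3.041509642843213, -0.7011827686858838, -0.7077052372953916),
    ("C1", "C", -4.007084284969589, -0.5711472438552762, -1.685074878198589),
    ("C1", "C", -5.306796641359122, -0.28844032687894455, -1.3307314136551298),
    ("C10", "C", -5.6388205657794055, -0.1553270775498004, -0.00329452123283),
    ("C1", "C", -4.684654763099289, -0.3108186949715912, 0.9751191061891656),
    ("C1", "C", -3.382974411311415, -0.5929653817459117, 0.6251083393699425),
    ("Cl", "Cl", -7.23938360644292, 0.19383575849239595, 0.43273272276431085),
    ("O4", "O", 4.531075600032757, -2.3981827864376637, 0.2112141449030358),
    ("C5", "C", 5.472651782937638, -1.5830975303167174, 0.8530170087008142),
    ("C6", "C", 1.4058269230923408, 2.1267150749457104, 1.2104025987372453),
    ("C8", "C", 2.10211944395565, 3.07907527794581, 0.30231541741987206),
    ("O1", "O", 1.9169778761045442, 3.258866052530957, -0.8716070224246035),
    ("O2", "O", 2.9908207851521644, 3.828888371928929, 0.9524452882955327),
    ("H1", "H", -0.9760130795313741, 2.846933264639907, -0.16994974048167816),
    ("H1", "H", -2.000143485461082, 1.7774005730770397, -1.0547188720404521),
    ("H1", "H", -2.089933914790547, 1.8411890366185015, 0.7045659710848718),
    ("H1", "H", 3.5210682841508585, 0.016178971409152757, 0.985174440049216),
    ("H1", "H", 2.762868561451652, -3.663582594017819, -0.9784646035550337),
    ("H1", "H", 0.4803024680168487, -2.9793735626365816, -1.4334120172931937),
    ("H1", "H", -3.749695654716189, -0.6931670204952817, -2.719428290946265),
    ("H1", "H", -6.053976594265562, -0.18225096246997274, -2.091392093955897),
    ("H1", "H", -4.95078573394969, -0.2221652158522312, 2.0094111209997285),
    ("H1", "H", -2.6504240073708485, -0.7348047563767058, 1.3949832367342245),
    ("H1", "H", 5.170229931296901, -1.3632410941521436, 1.8653720431346834),
    ("H1", "H", 6.4024214584998544, -2.127614387037679, 0.8998511851011745),
    ("H1", "H", 5.65074723793418, -0.6776065955440919, 0.29334711128027774),
    ("H1", "H", 0.6195710660568426, 2.663455050352692, 1.719801811768729),
    ("H1", "H", 2.105587744975526, 1.7892028254541237, 1.9614947058703556),
    ("H2", "H", 3.348567405235612, 4.404654545854777, 0.26281846410211845),
]

BONDS = [(0, 1), (0, 25), (0, 26), (0, 27), (1, 2), (1, 9), (2, 3), (2, 21), (3, 4), (3, 8), (4, 5), (4, 28), (5, 6), (5, 19), (6, 7), (6, 29), (7, 8), (7, 30), (8, 9), (9, 10), (10, 11), (10, 12), (12, 13), (12, 17), (13, 14), (13, 31), (14, 15), (14, 32), (15, 16), (15, 18), (16, 17), (16, 33), (17, 34), (19, 20), (20, 35), (20, 36), (20, 37), (21, 22), (21, 38), (21, 39), (22, 23), (22, 24), (24, 40)]

# name, (axis_a, axis_b), moved site ids
ROTATABLE_GROUPS = [
    ("chlorobenzyl_ring", (10, 12), [13, 14, 15, 16, 17, 18, 31, 32, 33, 34]),
    ("benzoyl", (9, 10), [11, 12, 13, 14, 15, 16, 17, 18, 31, 32, 33, 34]),
    ("methoxy", (5, 19), [20, 35, 36, 37]),
    ("acetic_arm", (2, 21), [22, 23, 24, 38, 39, 40]),
    ("carboxyl", (21, 22), [23, 24, 40]),
]
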