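"""Frozen 3D coordinates and bond graphs for the toy molecule library.

Generated once from SMILES with the package's own distance-geometry +
MMFF94 builder (seed 20240917) and frozen so every test sees identical
geometry regardless of dependency versions.  Synthetic data: these are
force-field geometries of real small molecules, not experimental or
quantum-chemical structures."""

TOY_DATA = {
    'water': {
        'smiles': 'O',
        'elements': ['O', 'H', 'H'],
        'coords': [(-0.001098, 0.397813, 0.000000), (0.764014, -0.196799, 0.000000), (-0.762916, -0.201015, 0.000000)],
        'bonds': [(0, 1, 1.0), (0, 2, 1.0)],
    },
    'ammonia': {
        'smiles': 'N',
        'elements': ['N', 'H', 'H', 'H'],
        'coords': [(0.000104, -0.001759, 0.295590), (-0.015047, 0.940144, -0.092934), (-0.806224, -0.482195, -0.101118), (0.821166, -0.456190, -0.101538)],
        'bonds': [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)],
    },
    'pyridine': {
        'smiles': 'c1ccncc1',
        'elements': ['C', 'C', 'C', 'N', 'C', 'C', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(0.079950, 1.180941, -0.023650), (1.229783, 0.398376, -0.039604), (1.085433, -0.979589, -0.010666), (-0.108950, -1.609293, 0.032227), (-1.207484, -0.823208, 0.046767), (-1.164786, 0.561690, 0.020376), (0.153298, 2.264371, -0.045345), (2.214506, 0.850256, -0.073737), (1.952682, -1.633404, -0.021536), (-2.154881, -1.353260, 0.081348), (-2.079553, 1.143120, 0.033819)],
        'bonds': [(0, 1, 1.5), (1, 2, 1.5), (2, 3, 1.5), (3, 4, 1.5), (4, 5, 1.5), (0, 5, 1.5), (0, 6, 1.0), (1, 7, 1.0), (2, 8, 1.0), (4, 9, 1.0), (5, 10, 1.0)],
    },
    'acetic_acid': {
        'smiles': 'CC(=O)O',
        'elements': ['C', 'C', 'O', 'O', 'H', 'H', 'H', 'H'],
        'coords': [(-0.955256, -0.120517, 0.033803), (0.469716, 0.318887, -0.036487), (0.871910, 1.465184, -0.134546), (1.329154, -0.715118, 0.020515), (-1.606918, 0.756373, -0.016521), (-1.183572, -0.774056, -0.811701), (-1.137481, -0.637015, 0.979393), (2.212448, -0.293738, -0.034457)],
        'bonds': [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0), (0, 4, 1.0), (0, 5, 1.0), (0, 6, 1.0), (3, 7, 1.0)],
    },
    'glycine': {
        'smiles': 'NCC(=O)O',
        'elements': ['N', 'C', 'C', 'O', 'O', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(-0.856896, 0.487465, -1.095723), (-0.445688, -0.611046, -0.204988), (0.861223, -0.291999, 0.507539), (1.707410, -1.098988, 0.858634), (0.996795, 1.017486, 0.820186), (-1.841837, 0.379681, -1.328637), (-0.771513, 1.361995, -0.571805), (-0.309217, -1.517752, -0.800863), (-1.211953, -0.785442, 0.556275), (1.871676, 1.058600, 1.259382)],
        'bonds': [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 2.0), (2, 4, 1.0), (0, 5, 1.0), (0, 6, 1.0), (1, 7, 1.0), (1, 8, 1.0), (4, 9, 1.0)],
    },
    'ethanolamine': {
        'smiles': 'NCCO',
        'elements': ['N', 'C', 'C', 'O', 'H', 'H', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(-1.226623, 0.809557, -0.265082), (-0.684145, -0.518820, 0.033227), (0.844944, -0.571059, -0.055547), (1.438667, 0.361904, 0.841883), (-0.993223, 1.450888, 0.490936), (-0.813232, 1.178147, -1.119402), (-1.114931, -1.244609, -0.663851), (-1.004829, -0.795145, 1.043458), (1.201157, -1.570445, 0.212313), (1.191988, -0.346703, -1.069769), (1.160228, 1.246285, 0.551833)],
        'bonds': [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (0, 4, 1.0), (0, 5, 1.0), (1, 6, 1.0), (1, 7, 1.0), (2, 8, 1.0), (2, 9, 1.0), (3, 10, 1.0)],
    },
    'thiolane_acetic_acid': {
        'smiles': 'OC(=O)CC1CCSC1',
        'elements': ['O', 'C', 'O', 'C', 'C', 'C', 'C', 'S', 'C', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(3.152519, 0.901505, -0.950302), (2.170614, -0.019789, -0.915238), (2.413229, -1.196277, -1.120080), (0.830702, 0.599258, -0.612887), (-0.293019, -0.451558, -0.551149), (-1.684607, 0.189565, -0.528200), (-1.912784, 0.767085, 0.859112), (-1.134516, -0.413746, 1.992459), (-0.227468, -1.323312, 0.705349), (3.961961, 0.384933, -1.148038), (0.616178, 1.312587, -1.417307), (0.915120, 1.150639, 0.329457), (-0.211643, -1.094037, -1.437363), (-2.443789, -0.575866, -0.738349), (-1.794449, 0.961645, -1.297422), (-2.977199, 0.880702, 1.081870), (-1.427746, 1.741568, 0.969946), (0.791301, -1.540850, 1.035929), (-0.744405, -2.274053, 0.538321)],
        'bonds': [(0, 1, 1.0), (1, 2, 2.0), (1, 3, 1.0), (3, 4, 1.0), (4, 5, 1.0), (5, 6, 1.0), (6, 7, 1.0), (7, 8, 1.0), (4, 8, 1.0), (0, 9, 1.0), (3, 10, 1.0), (3, 11, 1.0), (4, 12, 1.0), (5, 13, 1.0), (5, 14, 1.0), (6, 15, 1.0), (6, 16, 1.0), (8, 17, 1.0), (8, 18, 1.0)],
    },
    'bromoaminophenol': {
        'smiles': 'Nc1ccc(Br)cc1O',
        'elements': ['N', 'C', 'C', 'C', 'C', 'Br', 'C', 'C', 'O', 'H', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(-2.229792, -0.115091, -0.395576), (-0.845421, -0.156112, -0.139122), (-0.087206, -1.281436, -0.463390), (1.295757, -1.285566, -0.248756), (1.927385, -0.146086, 0.253548), (3.795738, -0.162494, 0.542082), (1.197565, 1.008778, 0.517060), (-0.172369, 0.998135, 0.286496), (-0.867277, 2.167086, 0.442738), (-2.728280, 0.384159, 0.339644), (-2.629310, -1.043246, -0.514607), (-0.561960, -2.170887, -0.868022), (1.870146, -2.178477, -0.481871), (1.680326, 1.915167, 0.867568), (-1.645302, 2.066070, -0.137792)],
        'bonds': [(0, 1, 1.0), (1, 2, 1.5), (2, 3, 1.5), (3, 4, 1.5), (4, 5, 1.0), (4, 6, 1.5), (6, 7, 1.5), (7, 8, 1.0), (1, 7, 1.5), (0, 9, 1.0), (0, 10, 1.0), (2, 11, 1.0), (3, 12, 1.0), (6, 13, 1.0), (8, 14, 1.0)],
    },
    'cysteine': {
        'smiles': 'NC(CS)C(=O)O',
        'elements': ['N', 'C', 'C', 'S', 'C', 'O', 'O', 'H', 'H', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(-0.172804, 1.556697, 0.951370), (-0.350629, 0.604633, -0.173144), (0.957510, -0.046093, -0.650447), (1.942061, -0.812808, 0.683472), (-1.380208, -0.468509, 0.192290), (-1.794038, -0.747142, 1.307156), (-1.835585, -1.143281, -0.885105), (-0.134978, 1.004972, 1.815378), (0.743823, 1.996577, 0.881205), (-0.779720, 1.181004, -1.001642), (1.592096, 0.713020, -1.120994), (0.759013, -0.816785, -1.402551), (2.940201, -1.253793, -0.096743), (-2.486741, -1.768493, -0.500246)],
        'bonds': [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (1, 4, 1.0), (4, 5, 2.0), (4, 6, 1.0), (0, 7, 1.0), (0, 8, 1.0), (1, 9, 1.0), (2, 10, 1.0), (2, 11, 1.0), (3, 12, 1.0), (6, 13, 1.0)],
    },
    'imidazole': {
        'smiles': 'c1c[nH]cn1',
        'elements': ['C', 'C', 'N', 'C', 'N', 'H', 'H', 'H', 'H'],
        'coords': [(1.072221, -0.586341, -0.210888), (0.698913, 0.719875, -0.000455), (-0.662960, 0.684473, 0.117667), (-1.053324, -0.616913, -0.023196), (-0.024830, -1.408365, -0.223110), (2.070605, -0.979095, -0.354129), (1.263944, 1.637791, 0.072758), (-1.275094, 1.472166, 0.279490), (-2.089475, -0.923590, 0.028818)],
        'bonds': [(0, 1, 1.5), (1, 2, 1.5), (2, 3, 1.5), (3, 4, 1.5), (0, 4, 1.5), (0, 5, 1.0), (1, 6, 1.0), (2, 7, 1.0), (3, 8, 1.0)],
    },
    'ethane': {
        'smiles': 'CC',
        'elements': ['C', 'C', 'H', 'H', 'H', 'H', 'H', 'H'],
        'coords': [(0.755549, -0.024803, 0.010484), (-0.755549, 0.024803, -0.010484), (1.173197, 0.671420, -0.722908), (1.135393, 0.247918, 0.999606), (1.110441, -1.031579, -0.229256), (-1.135392, -0.247916, -0.999606), (-1.173197, -0.671422, 0.722906), (-1.110441, 1.031578, 0.229257)],
        'bonds': [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0), (0, 4, 1.0), (1, 5, 1.0), (1, 6, 1.0), (1, 7, 1.0)],
    },
    'formamide': {
        'smiles': 'NC=O',
        'elements': ['N', 'C', 'O', 'H', 'H', 'H'],
        'coords': [(-0.688209, -0.068958, -0.038799), (0.659719, 0.081146, 0.043528), (1.451876, -0.778881, -0.307226), (-1.048940, -0.938244, -0.409828), (-1.335657, 0.648456, 0.253974), (0.961211, 1.056481, 0.458351)],
        'bonds': [(0, 1, 1.0), (1, 2, 2.0), (0, 3, 1.0), (0, 4, 1.0), (1, 5, 1.0)],
    },
}
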