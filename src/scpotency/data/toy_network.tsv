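G000	G001
G000	G002
G000	G003
G000	G004
G000	G022
G000	G032
G000	G046
G000	G050
G000	G055
G000	G069
G000	G070
G000	G076
G000	G095
G000	G100
G000	G107
G000	G138
G000	G141
G000	G157
G000	G171
G000	G198
G001	G004
G001	G005
G001	G007
G001	G014
G001	G068
G001	G081
G001	G154
G002	G005
G002	G006
G002	G008
G002	G009
G002	G010
G002	G011
G002	G016
G002	G030
G002	G039
G002	G047
G002	G170
G002	G196
G002	G198
G003	G004
G003	G006
G003	G009
G003	G021
G003	G033
G003	G046
G003	G070
G003	G071
G003	G072
G003	G075
G003	G087
G004	G005
G004	G008
G004	G013
G004	G055
G004	G056
G004	G057
G004	G088
G004	G115
G004	G166
G004	G176
G004	G179
G004	G185
G004	G198
G005	G006
G005	G007
G005	G008
G005	G016
G005	G017
G005	G030
G005	G032
G005	G034
G005	G042
G005	G046
G005	G053
G005	G074
G005	G077
G005	G090
G005	G094
G005	G114
G005	G119
G005	G128
G005	G134
G005	G136
G005	G142
G005	G149
G005	G158
G005	G174
G005	G187
G006	G007
G006	G010
G006	G011
G006	G015
G006	G017
G006	G020
G006	G029
G006	G032
G006	G035
G006	G044
G006	G047
G006	G050
G006	G052
G006	G058
G006	G090
G006	G098
G006	G117
G006	G118
G006	G121
G006	G129
G006	G139
G006	G159
G006	G165
G007	G012
G007	G014
G007	G019
G007	G020
G007	G021
G007	G022
G007	G024
G007	G025
G007	G037
G007	G042
G007	G048
G007	G059
G007	G062
G007	G064
G007	G080
G007	G091
G007	G093
G007	G094
G007	G095
G007	G097
G007	G108
G007	G113
G007	G123
G007	G130
G007	G140
G007	G142
G007	G146
G007	G179
G007	G180
G007	G181
G007	G182
G007	G190
G007	G191
G008	G009
G008	G010
G008	G017
G008	G023
G008	G025
G008	G027
G008	G028
G008	G031
G008	G040
G008	G041
G008	G043
G008	G051
G008	G080
G008	G085
G008	G091
G008	G101
G008	G114
G008	G120
G008	G127
G008	G128
G008	G144
G008	G151
G008	G158
G008	G159
G008	G162
G008	G170
G008	G182
G009	G013
G009	G016
G009	G018
G009	G019
G009	G024
G009	G026
G009	G028
G009	G033
G009	G043
G009	G048
G009	G133
G009	G190
G010	G011
G010	G012
G010	G018
G010	G045
G010	G066
G010	G083
G010	G098
G010	G113
G010	G116
G010	G126
G011	G012
G011	G013
G011	G014
G011	G015
G011	G018
G011	G019
G011	G020
G011	G022
G011	G027
G011	G029
G011	G031
G011	G035
G011	G036
G011	G038
G011	G043
G011	G047
G011	G049
G011	G052
G011	G053
G011	G054
G011	G057
G011	G059
G011	G060
G011	G068
G011	G075
G011	G078
G011	G079
G011	G080
G011	G082
G011	G088
G011	G089
G011	G090
G011	G092
G011	G097
G011	G101
G011	G105
G011	G106
G011	G117
G011	G121
G011	G124
G011	G131
G011	G133
G011	G135
G011	G141
G011	G143
G011	G155
G011	G159
G011	G175
G011	G178
G011	G196
G012	G015
G012	G026
G012	G034
G012	G041
G012	G061
G012	G169
G013	G023
G013	G024
G013	G042
G013	G049
G013	G052
G013	G054
G013	G096
G013	G116
G013	G124
G013	G133
G014	G040
G014	G123
G014	G137
G015	G039
G015	G040
G015	G062
G015	G119
G016	G051
G016	G065
G016	G083
G016	G087
G016	G153
G016	G161
G017	G034
G017	G050
G017	G073
G017	G076
G017	G081
G017	G082
G017	G085
G017	G088
G017	G099
G017	G111
G017	G145
G017	G147
G017	G156
G017	G190
G018	G021
G018	G023
G018	G027
G018	G028
G018	G056
G018	G057
G018	G060
G018	G061
G018	G110
G018	G176
G019	G029
G019	G044
G019	G066
G019	G127
G020	G025
G020	G038
G020	G049
G020	G058
G020	G059
G020	G065
G020	G071
G020	G093
G020	G115
G020	G125
G020	G130
G020	G140
G020	G160
G020	G173
G020	G181
G021	G033
G021	G037
G021	G062
G021	G067
G021	G096
G021	G143
G021	G147
G021	G197
G022	G026
G022	G030
G022	G036
G022	G044
G022	G048
G022	G092
G022	G158
G023	G037
G023	G199
G024	G045
G024	G076
G024	G081
G024	G083
G025	G109
G025	G110
G025	G117
G025	G138
G025	G188
G025	G199
G026	G056
G026	G129
G026	G135
G026	G192
G027	G031
G027	G038
G027	G041
G027	G063
G027	G195
G028	G036
G028	G191
G029	G055
G029	G060
G029	G065
G029	G086
G029	G145
G029	G153
G029	G168
G029	G193
G030	G086
G031	G068
G031	G082
G031	G122
G031	G151
G032	G035
G033	G084
G033	G089
G033	G111
G033	G145
G033	G167
G034	G150
G035	G118
G035	G122
G035	G139
G035	G164
G035	G176
G036	G066
G036	G096
G036	G155
G038	G039
G038	G045
G038	G063
G038	G071
G038	G073
G038	G092
G038	G102
G038	G107
G038	G118
G038	G140
G038	G163
G038	G174
G039	G074
G039	G079
G039	G084
G039	G148
G039	G199
G040	G111
G041	G061
G041	G067
G041	G102
G041	G103
G041	G116
G041	G148
G041	G166
G042	G072
G042	G084
G042	G100
G042	G135
G042	G141
G042	G165
G042	G187
G042	G191
G043	G103
G044	G051
G044	G086
G044	G150
G044	G172
G045	G173
G045	G184
G046	G075
G046	G137
G046	G180
G047	G108
G047	G120
G048	G125
G048	G136
G048	G155
G048	G182
G048	G196
G049	G073
G049	G091
G049	G131
G049	G194
G050	G053
G050	G054
G050	G063
G050	G112
G050	G120
G050	G130
G050	G134
G050	G168
G050	G174
G051	G105
G051	G109
G052	G099
G052	G147
G052	G165
G052	G193
G053	G064
G053	G103
G053	G112
G054	G072
G054	G078
G054	G097
G054	G098
G054	G149
G054	G168
G054	G175
G054	G189
G054	G197
G055	G058
G055	G105
G055	G172
G056	G109
G056	G157
G056	G173
G058	G157
G058	G183
G058	G197
G059	G077
G059	G132
G060	G069
G060	G131
G061	G067
G061	G070
G062	G064
G063	G099
G064	G152
G065	G077
G065	G094
G065	G122
G066	G177
G067	G107
G068	G069
G068	G087
G068	G113
G068	G126
G068	G129
G068	G149
G068	G192
G069	G177
G070	G079
G070	G101
G071	G074
G073	G078
G073	G108
G073	G156
G074	G104
G074	G144
G074	G186
G075	G089
G075	G136
G076	G093
G079	G100
G081	G124
G081	G146
G081	G163
G082	G104
G082	G106
G082	G156
G083	G085
G083	G123
G083	G171
G084	G114
G084	G162
G085	G153
G087	G151
G087	G184
G088	G102
G088	G152
G088	G164
G089	G154
G090	G095
G090	G106
G090	G167
G090	G195
G091	G121
G092	G163
G092	G180
G093	G144
G094	G110
G094	G132
G095	G139
G096	G137
G096	G194
G099	G178
G100	G104
G100	G125
G101	G119
G101	G150
G101	G169
G102	G127
G103	G126
G104	G115
G105	G134
G106	G112
G110	G177
G111	G142
G111	G152
G111	G166
G113	G128
G113	G172
G113	G188
G114	G167
G114	G185
G114	G193
G117	G162
G117	G170
G118	G143
G118	G148
G118	G169
G119	G184
G120	G175
G122	G132
G122	G138
G122	G160
G123	G161
G124	G146
G124	G171
G125	G183
G128	G154
G130	G160
G130	G164
G141	G194
G142	G188
G143	G181
G144	G183
G152	G161
G153	G186
G156	G185
G157	G178
G157	G189
G167	G179
G172	G189
G173	G195
G176	G187
G180	G186
G185	G192
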