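gene,sp,ird1,ird2,ird3,ird4,partial,novel,count_UL,count_AI,count_WW,count_WOS
CanPI-1,5,4,5,10,,0,0,2,1,,
CanPI-2,2,1,16,13,,0,0,,,,1
CanPI-3,1,1,1,17,,0,0,3,3,2,1
CanPI-4,1,1,25,17,,0,0,,3,1,11
CanPI-5,4,1,1,17,,0,0,6,1,3,3
CanPI-6,,2,25,17,p,1,0,,,,
CanPI-7,5,4,14,5,10,0,0,1,5,1,12
CanPI-8,5,4,14,3,10,0,0,,,2,3
CanPI-9,1,1,25,5,10,0,0,,,,
CanPI-10,5,4,14,5,8,0,0,2,,3,6
CanPI-11,1,4,14,5,10,0,0,,,3,1
CanPI-12,,1,1,11p,,1,0,,,,
CanPI-13,1,17,,,,0,0,1,,,
CanPI-14,1,6,,,,0,0,,,,
CanPI-15,5,7,,,,0,0,2,,,
CanPI-16,1,1,17,,,0,0,1,,,
CanPI-17,1,12,17,,,0,0,1,1,1,1
CanPI-18,1,25,17,,,0,0,1,,,
CanPI-19,1,1,25,,,0,0,,,,
CanPI-20,1,25,17,,,0,0,,,,3
CanPI-21,5,4,17,,,0,0,1,,,
CanPI-22,5,4,9,,,0,0,,1,2,2
CanPI-23,3,25,17,,,0,0,1,,,
CanPI-24,1,1,18,,,0,1,,5,4,
CanPI-25,3,1,18,,,0,1,,2,,
CanPI-26,5,4,10,,,0,1,,4,1,
CanPI-27,5,23,18,,,0,1,,,1,
CanPI-28,8,22,18,,,0,1,,,1,
CanPI-29,6,21,18,,,0,1,,,1,
CanPI-30,7,1,17,,,0,1,,,1,
CanPI-31,1,1,12,27,17,0,1,,1,,1
CanPI-32,5,4,14,5,10,0,1,,1,,
CanPI-33,8,24,1,12,17,0,1,,,1,
CanPI-34,1,1,12,17,,0,1,,,1,
CanPI-35,8,1,12,17,,0,1,,,1,
CanPI-36,8,5,37,18,,0,1,,,1,
CanPI-37,8,33,37,48,,0,1,1,,2,3
CanPI-38,9,5,40,17,,0,1,,,1,
CanPI-39,8,5,12,17,,0,1,,1,,
CanPI-40,5,5,37,18,,0,1,,1,,
CanPI-41,8,5,37,18,,0,1,,10,4,5
CanPI-42,5,4,1,17,,0,1,,1,,
CanPI-43,1,1,12,17,,0,1,2,11,4,4
CanPI-44,1,1,12,17,,0,1,,1,,
CanPI-45,10,1,12,18,,0,1,,,2,
CanPI-46,1,4,37,18,,0,1,,1,1,1
CanPI-47,1,1,1,55,,0,1,,,1,2
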