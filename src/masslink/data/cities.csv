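city,state
Birmingham,AL
Montgomery,AL
Mobile,AL
Huntsville,AL
Anchorage,AK
Phoenix,AZ
Tucson,AZ
Mesa,AZ
Little Rock,AR
Fayetteville,AR
Los Angeles,CA
San Diego,CA
San Jose,CA
San Francisco,CA
Fresno,CA
Sacramento,CA
Long Beach,CA
Oakland,CA
Bakersfield,CA
Anaheim,CA
Stockton,CA
Riverside,CA
Denver,CO
Colorado Springs,CO
Aurora,CO
Bridgeport,CT
New Haven,CT
Hartford,CT
Wilmington,DE
Dover,DE
Washington,DC
Jacksonville,FL
Miami,FL
Tampa,FL
Orlando,FL
St. Petersburg,FL
Hialeah,FL
Tallahassee,FL
Fort Lauderdale,FL
Atlanta,GA
Augusta,GA
Columbus,GA
Savannah,GA
Macon,GA
Honolulu,HI
Boise,ID
Chicago,IL
Aurora,IL
Rockford,IL
Joliet,IL
Springfield,IL
Peoria,IL
Indianapolis,IN
Fort Wayne,IN
Evansville,IN
Gary,IN
Des Moines,IA
Cedar Rapids,IA
Wichita,KS
Kansas City,KS
Topeka,KS
Louisville,KY
Lexington,KY
New Orleans,LA
Baton Rouge,LA
Shreveport,LA
Lafayette,LA
Portland,ME
Baltimore,MD
Annapolis,MD
Boston,MA
Worcester,MA
Springfield,MA
Detroit,MI
Grand Rapids,MI
Flint,MI
Lansing,MI
Minneapolis,MN
Saint Paul,MN
Jackson,MS
Gulfport,MS
Kansas City,MO
St. Louis,MO
Springfield,MO
Columbia,MO
Billings,MT
Omaha,NE
Lincoln,NE
Las Vegas,NV
Reno,NV
Henderson,NV
Manchester,NH
Newark,NJ
Jersey City,NJ
Paterson,NJ
Trenton,NJ
Camden,NJ
Albuquerque,NM
Las Cruces,NM
Santa Fe,NM
New York,NY
Buffalo,NY
Rochester,NY
Syracuse,NY
Albany,NY
Yonkers,NY
Charlotte,NC
Raleigh,NC
Greensboro,NC
Durham,NC
Winston-Salem,NC
Fayetteville,NC
Fargo,ND
Columbus,OH
Cleveland,OH
Cincinnati,OH
Toledo,OH
Akron,OH
Dayton,OH
Youngstown,OH
Oklahoma City,OK
Tulsa,OK
Norman,OK
Portland,OR
Eugene,OR
Salem,OR
Philadelphia,PA
Pittsburgh,PA
Allentown,PA
Erie,PA
Reading,PA
Harrisburg,PA
Providence,RI
Columbia,SC
Charleston,SC
North Charleston,SC
Greenville,SC
Sioux Falls,SD
Memphis,TN
Nashville,TN
Knoxville,TN
Chattanooga,TN
Houston,TX
San Antonio,TX
Dallas,TX
Austin,TX
Fort Worth,TX
El Paso,TX
Arlington,TX
Corpus Christi,TX
Laredo,TX
Lubbock,TX
Odessa,TX
Waco,TX
Beaumont,TX
Salt Lake City,UT
Provo,UT
West Valley City,UT
Burlington,VT
Virginia Beach,VA
Norfolk,VA
Richmond,VA
Chesapeake,VA
Newport News,VA
Roanoke,VA
Seattle,WA
Spokane,WA
Tacoma,WA
Vancouver,WA
Everett,WA
Charleston,WV
Huntington,WV
Milwaukee,WI
Madison,WI
Green Bay,WI
Kenosha,WI
Racine,WI
Cheyenne,WY
Casper,WY
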